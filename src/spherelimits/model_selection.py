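"""Nested-model F-tests and sphere detection-limit grids.

The sphere compartment is considered detectable when the three-compartment
(stick+ball+sphere) fit improves on the nested two-compartment (stick+ball)
fit by more than chance, as judged by

    F = (SSR₁ − SSR₂)(N − M₂) / (SSR₂ (M₂ − M₁)),     p = 1 − F_cdf(F),

with N the number of fitted powder points and M₁ < M₂ the free-parameter
counts.  Detection grids sweep sphere fraction, radius and SNR with several
noise replicates per cell; a cell counts as detected when the majority of
replicate p-values fall below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import fit_model
from .signal_models import TissueParams
from .synthetic_data import default_protocol, generate_dataset

__all__ = [
    "FTestResult",
    "DetectionGrid",
    "f_test",
    "detection_experiment",
    "detection_grid",
    "sphere_fraction_lower_bound",
    "sphere_radius_lower_bound",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class FTestResult:
    f_stat: float
    p_value: float
    df1: int
    df2: int
    preferred: str  # "simple" | "full"


def f_test(ssr_simple: float, ssr_full: float, m_simple: int, m_full: int,
           n_points: int, alpha: float = ALPHA_DEFAULT) -> FTestResult:
    """F-test between a simple model and a full model nested above it.

    The nesting premise requires SSR_full ≤ SSR_simple; an optimizer that
    lands above the simple model's SSR (flat landscape) violates it, in
    which case F is clamped to zero (the full model earns no support).
    """
    df1 = m_full - m_simple
    df2 = n_points - m_full
    if df1 <= 0 or df2 <= 0:
        raise ValueError(
            f"degenerate degrees of freedom: df1={df1}, df2={df2}"
        )
    if ssr_full <= 0:
        f_stat = np.inf if ssr_simple > ssr_full else 0.0
    else:
        f_stat = (ssr_simple - ssr_full) * df2 / (ssr_full * df1)
    f_stat = max(float(f_stat), 0.0)
    p = float(stats.f.sf(f_stat, df1, df2))
    return FTestResult(
        f_stat=f_stat,
        p_value=p,
        df1=df1,
        df2=df2,
        preferred="full" if p < alpha else "simple",
    )


def _ground_truth(f_sphere: float, r_sphere: float, d_par: float,
                  d_ball: float) -> TissueParams:
    rest = (1.0 - f_sphere) / 2.0
    return TissueParams(
        f_stick=rest, f_ball=rest, f_sphere=f_sphere,
        d_par=d_par, d_ball=d_ball, r_sphere=r_sphere,
    )


def detection_experiment(
    f_sphere: float,
    r_sphere: float,
    snr: float = 50.0,
    n_reps: int = 10,
    seed: int = 0,
    scenario: str = "rician",
    protocol=None,
    d_par: float = 2.0,
    d_ball: float = 0.6,
    n_starts: int = 8,
    rician_floor: bool = False,
    mode: str = "presence",
) -> dict:
    """Replicate-level nested-model comparison for one (f, R, SNR) cell.

    Each replicate simulates a noisy dataset at the ground truth
    f_ball = f_stick = (1 − f_sphere)/2 and runs a nested F-test.  Two
    nestings probe two different questions:

    * ``mode="presence"`` — stick+ball versus stick+ball+sphere: is a
      spherical compartment present at all?  This drives the signal-
      *fraction* detection limit.  Note that at a large sphere fraction the
      comparison succeeds at every radius, because even an unattenuated
      (R → 0) sphere is a constant signal offset that stick+ball cannot
      mimic.
    * ``mode="size"`` — stick+ball+sphere with the radius pinned to the
      zero-size ("dot") limit versus radius free: does the signal carry
      information about the sphere's *size*?  This drives the radius
      sensitivity floor; below it, spheres are indistinguishable from
      dots because their attenuation is negligible.

    The larger model's fit always includes a warm start at the smaller
    model's solution, preserving the SSR nesting by construction.  Failed
    replicates are excluded and counted.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if mode not in ("presence", "size"):
        raise ValueError(f"unknown mode {mode!r}")
    if protocol is None:
        protocol = default_protocol()
    truth = _ground_truth(f_sphere, r_sphere, d_par, d_ball)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    rows = []
    n_failed = 0
    for rep, child in enumerate(children):
        fit_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        try:
            data = generate_dataset(
                truth, protocol, model="stick_ball_sphere", snr=snr,
                scenario=scenario, seed=child,
            )
            if mode == "presence":
                simple = fit_model(
                    data, protocol, "stick_ball", n_starts=n_starts,
                    seed=fit_seed, rician_floor=rician_floor,
                )
                warm = np.concatenate([[0.0], simple.x[:3], [5.0]])
                if rician_floor:
                    warm = np.concatenate([warm, simple.x[3:]])
            else:
                simple = fit_model(
                    data, protocol, "stick_ball_sphere",
                    fixed={"r_sphere": 0.0}, n_starts=n_starts,
                    seed=fit_seed, rician_floor=rician_floor,
                )
                warm = np.concatenate([simple.x[:4], [5.0]])
                if rician_floor:
                    warm = np.concatenate([warm, simple.x[4:]])
            full = fit_model(
                data, protocol, "stick_ball_sphere", n_starts=n_starts,
                seed=fit_seed + 1, x0_extra=[warm],
                rician_floor=rician_floor,
            )
            ft = f_test(
                simple.ssr, full.ssr, simple.n_params, full.n_params,
                data.n_points,
            )
        except Exception:  # noqa: BLE001 - excluded replicates are counted
            n_failed += 1
            continue
        rows.append(
            {
                "fsphere": f_sphere,
                "rsphere": r_sphere,
                "snr": snr,
                "rep": rep,
                "p": ft.p_value,
                "fstat": ft.f_stat,
                "rhat": full.estimates.r_sphere,
                "fhat": full.estimates.f_sphere,
            }
        )
    table = pd.DataFrame(rows)
    detected = table["p"] < ALPHA_DEFAULT if len(table) else pd.Series(dtype=bool)
    return {
        "table": table,
        "n_failed": n_failed,
        "median_p": float(table["p"].median()) if len(table) else np.nan,
        "median_rhat": float(table["rhat"].median()) if len(table) else np.nan,
        "detection_fraction": float(detected.mean()) if len(table) else np.nan,
        "detected": bool(detected.mean() > 0.5) if len(table) else False,
    }


@dataclass
class DetectionGrid:
    """Long-format replicate table over (f_sphere, r_sphere, snr) cells."""

    f_sphere_values: np.ndarray
    r_sphere_values: np.ndarray
    snr_values: np.ndarray
    table: pd.DataFrame  # columns fsphere,rsphere,snr,rep,p,fstat,rhat,fhat
    n_failed: int = 0

    def cell_summary(self) -> pd.DataFrame:
        grouped = self.table.groupby(["fsphere", "rsphere", "snr"])
        out = grouped.agg(
            median_p=("p", "median"),
            median_rhat=("rhat", "median"),
            median_fhat=("fhat", "median"),
            detection_fraction=("p", lambda p: float((p < ALPHA_DEFAULT).mean())),
            n_reps=("p", "size"),
        ).reset_index()
        return out


def detection_grid(
    f_sphere_values,
    r_sphere_values,
    snr_values=(50.0,),
    n_reps: int = 10,
    seed: int = 0,
    scenario: str = "rician",
    protocol=None,
    **kwargs,
) -> DetectionGrid:
    """Run :func:`detection_experiment` over a full parameter grid."""
    f_vals = np.asarray(f_sphere_values, dtype=float)
    r_vals = np.asarray(r_sphere_values, dtype=float)
    s_vals = np.asarray(snr_values, dtype=float)
    for name, vals in (("f_sphere", f_vals), ("r_sphere", r_vals),
                       ("snr", s_vals)):
        if np.any(np.diff(vals) <= 0):
            raise ValueError(f"{name} grid values must be strictly increasing")
    if protocol is None:
        protocol = default_protocol()
    master = np.random.SeedSequence(seed)
    tables = []
    n_failed = 0
    cells = [(f, r, s) for s in s_vals for r in r_vals for f in f_vals]
    for child, (f, r, s) in zip(master.spawn(len(cells)), cells):
        cell_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        cell = detection_experiment(
            f, r, snr=s, n_reps=n_reps, seed=cell_seed, scenario=scenario,
            protocol=protocol, **kwargs,
        )
        tables.append(cell["table"])
        n_failed += cell["n_failed"]
    return DetectionGrid(
        f_sphere_values=f_vals,
        r_sphere_values=r_vals,
        snr_values=s_vals,
        table=pd.concat(tables, ignore_index=True),
        n_failed=n_failed,
    )


def _lower_bound(summary: pd.DataFrame, axis: str):
    hits = summary[summary["detection_fraction"] > 0.5]
    if hits.empty:
        return None
    return float(hits[axis].min())


def sphere_fraction_lower_bound(grid: DetectionGrid, r_fixed: float,
                                snr: float | None = None):
    """Smallest f_sphere with majority detection at the given radius.

    Returns None ("above grid") when no cell along the row is detected;
    the resolution is the grid spacing around the returned value.
    """
    summary = grid.cell_summary()
    if not np.any(np.isclose(grid.r_sphere_values, r_fixed)):
        raise ValueError(f"radius {r_fixed} is not on the grid")
    sel = summary[np.isclose(summary["rsphere"], r_fixed)]
    if snr is not None:
        sel = sel[np.isclose(sel["snr"], snr)]
    return _lower_bound(sel, "fsphere")


def sphere_radius_lower_bound(grid: DetectionGrid, f_fixed: float,
                              snr: float | None = None):
    """Smallest radius with majority detection at the given sphere fraction."""
    summary = grid.cell_summary()
    if not np.any(np.isclose(grid.f_sphere_values, f_fixed)):
        raise ValueError(f"fraction {f_fixed} is not on the grid")
    sel = summary[np.isclose(summary["fsphere"], f_fixed)]
    if snr is not None:
        sel = sel[np.isclose(sel["snr"], snr)]
    return _lower_bound(sel, "rsphere")
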