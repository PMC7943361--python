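"""Fit per-node CV_max / APD_max fields from sparse electrode recordings and
validate the resulting model against held-out activation times.

The workflow mirrors clinical model personalization: local conduction
velocity is estimated from activation-time plane fits around each electrode,
the refractory period serves as the APD_max surrogate, the sparse estimates
are interpolated to every node, and the personalized model is validated by
comparing simulated and "measured" activation times at a pacing site that
was not used for fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .mms_model import MMSParameters, ParameterFieldSet
from .tissue import TissueDomain

#: electrodes snap to the nearest domain node within this distance
SNAP_TOLERANCE_MM = 2.0


def local_cv_from_lat(table: pd.DataFrame, neighborhood_radius: float = 15.0,
                      s2_select: str = "max") -> pd.DataFrame:
    """Per-site conduction velocity (cm/s) from local plane fits to LAT.

    For each site, the activation times of all sites within
    ``neighborhood_radius`` mm are fitted with a travelling plane
    T(x) = a.x + b; the local speed is 1/|a|.  Uses the longest S2
    (fully recovered tissue) by default, so the estimate approximates
    CV_max.  Ill-conditioned neighbourhoods (fewer than 3 sites, or
    collinear) are flagged rather than fatal.
    """
    if s2_select == "max":
        s2 = table["s2_ms"].max()
    else:
        s2 = float(s2_select)
    sub = table[table["s2_ms"] == s2].reset_index(drop=True)
    pos = sub[["x_mm", "y_mm", "z_mm"]].to_numpy()
    lat = sub["lat_ms"].to_numpy()
    tree = cKDTree(pos)
    rows = []
    for i in range(len(sub)):
        nbrs = tree.query_ball_point(pos[i], neighborhood_radius)
        flagged = False
        cv = np.nan
        if len(nbrs) < 3:
            flagged = True
        else:
            X = pos[nbrs] - pos[nbrs].mean(axis=0)
            y = lat[nbrs] - lat[nbrs].mean()
            # drop degenerate axes (e.g. planar z = const)
            keep = np.ptp(X, axis=0) > 1e-9
            if keep.sum() < 2:
                flagged = True
            else:
                Xk = X[:, keep]
                sv = np.linalg.svd(Xk, compute_uv=False)
                if sv[-1] < 1e-6 * sv[0]:
                    flagged = True  # collinear neighbourhood
                else:
                    a, *_ = np.linalg.lstsq(Xk, y, rcond=None)
                    slow = np.linalg.norm(a)  # ms/mm
                    if slow < 1e-9:
                        flagged = True
                    else:
                        cv = 100.0 / slow  # mm/ms -> cm/s
        rows.append({"site_id": sub["site_id"].iloc[i],
                     "x_mm": pos[i, 0], "y_mm": pos[i, 1], "z_mm": pos[i, 2],
                     "cv_cm_s": cv, "flagged": flagged})
    return pd.DataFrame(rows)


def apdmax_from_erp(erp, delta: float = 0.0):
    """APD_max estimate from the refractory period: ERP - delta.

    With the default delta = 0 the ERP is used directly as the surrogate.
    """
    erp = np.asarray(erp, dtype=float)
    if np.any(erp <= 0):
        raise ValueError("ERP values must be positive")
    out = erp - delta
    if np.any(out <= 0):
        raise ValueError(
            f"delta = {delta} ms drives the APD_max estimate non-positive")
    return out if out.ndim else float(out)


def interpolate_fields(site_positions, site_values, domain: TissueDomain,
                       power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted interpolation of sparse site values to every
    node.  Exact at site nodes and bounded by [min, max] of the inputs."""
    site_positions = np.asarray(site_positions, dtype=float)
    site_values = np.asarray(site_values, dtype=float)
    valid = np.isfinite(site_values)
    if not np.any(valid):
        raise ValueError("no valid site values to interpolate")
    site_positions = site_positions[valid]
    site_values = site_values[valid]
    d = np.linalg.norm(
        domain.positions[:, None, :] - site_positions[None, :, :], axis=2)
    out = np.empty(domain.n_nodes)
    at_site = d < 1e-9
    exact = at_site.any(axis=1)
    out[exact] = site_values[np.argmax(at_site[exact], axis=1)]
    w = 1.0 / np.maximum(d[~exact], 1e-12) ** power
    out[~exact] = (w @ site_values) / w.sum(axis=1)
    return out


def fields_from_recordings(
    table: pd.DataFrame,
    domain: TissueDomain,
    base_params: MMSParameters | None = None,
    neighborhood_radius: float = 15.0,
    erp_delta: float = 0.0,
    dx: float | None = None,
) -> ParameterFieldSet:
    """End-to-end personalization: electrode table -> per-node fields."""
    cv_tab = local_cv_from_lat(table, neighborhood_radius)
    ok = ~cv_tab["flagged"]
    if not ok.any():
        raise ValueError("all CV estimates are flagged; cannot personalize")
    pos = cv_tab.loc[ok, ["x_mm", "y_mm", "z_mm"]].to_numpy()
    cv_nodes = interpolate_fields(pos, cv_tab.loc[ok, "cv_cm_s"].to_numpy(), domain)
    erp_sites = table.groupby("site_id").first()
    apd_sites = apdmax_from_erp(erp_sites["erp_ms"].to_numpy(), erp_delta)
    apd_nodes = interpolate_fields(
        erp_sites[["x_mm", "y_mm", "z_mm"]].to_numpy(), apd_sites, domain)
    base_params = base_params or MMSParameters()
    if dx is None:
        dx = domain.spacing if domain.spacing is not None else 0.5
    return ParameterFieldSet.from_targets(cv_nodes, apd_nodes, base_params, dx=dx)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class FitReport:
    """Regression of predicted on measured LAT, pooled over S2 values."""
    slope: float
    intercept: float
    correlation: float
    rmse: float
    n_pairs: int
    per_s2: dict

    def __post_init__(self):
        if not np.isfinite(self.slope):
            raise ValueError("regression slope is not finite")
        if self.rmse < 0:
            raise ValueError("RMSE must be non-negative")


def _regress(measured: np.ndarray, predicted: np.ndarray) -> dict:
    if np.ptp(measured) < 1e-12:
        slope, intercept, r = np.nan, np.nan, np.nan
    else:
        res = stats.linregress(measured, predicted)
        slope, intercept, r = res.slope, res.intercept, res.rvalue
    rmse = float(np.sqrt(np.mean((predicted - measured) ** 2)))
    return {"slope": float(slope), "intercept": float(intercept),
            "correlation": float(r), "rmse": rmse, "n_pairs": len(measured)}


def validate_lat(predicted: dict, measured: pd.DataFrame,
                 domain: TissueDomain,
                 snap_tolerance: float = SNAP_TOLERANCE_MM) -> FitReport:
    """Compare predicted activation maps with measured electrode LATs.

    ``predicted`` maps S2 value -> ActivationMap from the simulated pacing
    protocol; measured sites snap to the nearest node within
    ``snap_tolerance`` mm.  Returns the pooled least-squares line plus
    per-S2 sub-reports.
    """
    tree = cKDTree(domain.positions)
    pairs_m, pairs_p, per_s2 = [], [], {}
    for s2, grp in measured.groupby("s2_ms"):
        if s2 not in predicted:
            continue
        amap = predicted[s2]
        d, nodes = tree.query(grp[["x_mm", "y_mm", "z_mm"]].to_numpy())
        if np.any(d > snap_tolerance):
            bad = grp["site_id"].to_numpy()[d > snap_tolerance]
            raise ValueError(
                f"electrode site(s) {bad.tolist()} farther than "
                f"{snap_tolerance} mm from any node")
        pred = amap.lat[nodes]
        meas = grp["lat_ms"].to_numpy()
        good = np.isfinite(pred) & np.isfinite(meas)
        if good.sum() >= 2:
            per_s2[float(s2)] = _regress(meas[good], pred[good])
        pairs_m.append(meas[good])
        pairs_p.append(pred[good])
    m = np.concatenate(pairs_m) if pairs_m else np.array([])
    p = np.concatenate(pairs_p) if pairs_p else np.array([])
    if len(m) < 2:
        raise ValueError(f"need >= 2 (measured, predicted) pairs, got {len(m)}")
    pooled = _regress(m, p)
    return FitReport(**pooled, per_s2=per_s2)


def refine_global_params(
    table: pd.DataFrame,
    domain: TissueDomain,
    simulate_validation,
    base_params: MMSParameters | None = None,
    scales=(0.85, 1.0, 1.15),
    n_sweeps: int = 1,
) -> MMSParameters:
    """Optional per-case scalar refinement of the globally fixed cell
    parameters (v_gate, tau_open, tau_in) by coordinate descent on the
    validation RMSE.

    ``simulate_validation(params) -> FitReport`` must rebuild fields with the
    candidate globals and validate at the held-out pacing site; the
    per-node identifiability of these three parameters is not established,
    so only case-level scalars are adjusted.
    """
    best = base_params or MMSParameters()
    best_rmse = simulate_validation(best).rmse
    for _ in range(n_sweeps):
        for name in ("v_gate", "tau_open", "tau_in"):
            for s in scales:
                if s == 1.0:
                    continue
                cand = replace(best, **{name: getattr(best, name) * s})
                try:
                    rmse = simulate_validation(cand).rmse
                except (ValueError, RuntimeError):
                    continue
                if rmse < best_rmse:
                    best, best_rmse = cand, rmse
    return best
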