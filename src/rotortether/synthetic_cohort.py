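"""Synthetic cohort generation.

Clinical atrial data sets of this kind cannot be shared, so this module
produces synthetic stand-ins with the statistical structure the analysis
assumes: spatially correlated CV_max / APD_max fields with a localized
slow-CV / short-APD patch (the arrhythmogenic substrate), cohorts of cases
spanning a range of atrial surface areas, sparse virtual-electrode
recordings generated by forward simulation plus noise, and a reference
cohort-characteristics table packaged as a fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from .mms_model import MMSParameters, ParameterFieldSet, erp_single_cell
from .tissue import TissueDomain, make_sheet_domain, make_mesh_domain, gaussian_smoothing_matrix

__all__ = [
    "CohortRecord", "SubstratePatchSpec", "CohortCase",
    "make_sheet_domain", "make_mesh_domain",
    "sample_parameter_fields", "make_virtual_cohort",
    "synth_electrode_recordings", "load_cohort_table", "summarize_cohort",
]


@dataclass(frozen=True)
class CohortRecord:
    """One case of the cohort-characteristics table."""
    case_id: int
    age_years: float
    sex: str                 # "M" | "F"
    af_duration_years: float
    af_class: str            # "PAF" | "PsAF"
    la_diameter_cm: float
    lvef_pct: float
    surface_cm2: float

    def __post_init__(self):
        if self.af_class not in ("PAF", "PsAF"):
            raise ValueError(f"af_class must be PAF or PsAF, got {self.af_class}")
        if self.surface_cm2 <= 0:
            raise ValueError(f"surface must be > 0, got {self.surface_cm2}")


@dataclass(frozen=True)
class SubstratePatchSpec:
    """A localized slow-conduction / short-APD patch with a smooth edge.

    ``cv_scale`` multiplies CV_max inside the patch (< 1 slows conduction),
    ``apd_offset`` (ms, <= 0) shortens APD_max.  The surrounding fields are
    modulated by a correlated Gaussian random field with the given
    correlation length and fractional noise SDs.
    """
    center: tuple[float, float]       # mm
    radius: float                     # mm
    cv_scale: float = 1.0
    apd_offset: float = 0.0           # ms
    correlation_length: float = 10.0  # mm
    cv_noise_sd: float = 0.0          # fractional
    apd_noise_sd: float = 0.0         # fractional

    def __post_init__(self):
        if not 0 < self.cv_scale <= 1:
            raise ValueError(f"cv_scale must lie in (0, 1], got {self.cv_scale}")
        if self.radius <= 0:
            raise ValueError(f"patch radius must be > 0, got {self.radius}")
        if self.apd_offset > 0:
            raise ValueError(f"apd_offset must be <= 0 ms, got {self.apd_offset}")


def _correlated_noise(domain: TissueDomain, corr_len: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-SD, zero-mean Gaussian random field with the given correlation
    length, built by Gaussian-smoothing white noise."""
    white = rng.standard_normal(domain.n_nodes)
    if corr_len <= 0:
        return white
    if domain.kind == "sheet":
        ny, nx = domain.shape
        smooth = ndimage.gaussian_filter(
            white.reshape(ny, nx), sigma=corr_len / domain.spacing,
            mode="nearest").ravel()
    else:
        S = gaussian_smoothing_matrix(domain, corr_len)
        smooth = S.T @ white
    sd = smooth.std()
    if sd < 1e-30:
        return np.zeros_like(smooth)
    return (smooth - smooth.mean()) / sd


def patch_taper(domain: TissueDomain, patch: SubstratePatchSpec) -> np.ndarray:
    """Patch membership weight in [0, 1]: 1 in the core, cosine taper to 0
    over the outer 20 % of the radius (avoids numerically induced wave
    breaks at hard parameter discontinuities)."""
    d = np.linalg.norm(domain.positions[:, :2] - np.asarray(patch.center), axis=1)
    r0 = 0.8 * patch.radius
    w = np.zeros(domain.n_nodes)
    w[d <= r0] = 1.0
    edge = (d > r0) & (d < patch.radius)
    w[edge] = 0.5 * (1.0 + np.cos(np.pi * (d[edge] - r0) / (patch.radius - r0)))
    return w


def sample_parameter_fields(
    domain: TissueDomain,
    base_cv: float,
    base_apd: float,
    patch: SubstratePatchSpec,
    seed: int,
    base_params: MMSParameters | None = None,
    dx: float | None = None,
) -> ParameterFieldSet:
    """Per-node CV_max / APD_max fields: base value times smooth correlated
    noise, with the patch applied multiplicatively (CV) and additively (APD).
    Deterministic given ``seed``."""
    if base_cv <= 0:
        raise ValueError(f"base_cv must be > 0, got {base_cv}")
    if base_apd <= 0:
        raise ValueError(f"base_apd must be > 0, got {base_apd}")
    lo, hi = domain.bounding_box()
    cx, cy = patch.center
    if not (lo[0] <= cx <= hi[0] and lo[1] <= cy <= hi[1]):
        raise ValueError(f"patch center {patch.center} lies outside the domain")
    rng = np.random.default_rng(seed)
    cv = base_cv * (1.0 + patch.cv_noise_sd *
                    _correlated_noise(domain, patch.correlation_length, rng))
    apd = base_apd * (1.0 + patch.apd_noise_sd *
                      _correlated_noise(domain, patch.correlation_length, rng))
    w = patch_taper(domain, patch)
    cv = cv * (1.0 - (1.0 - patch.cv_scale) * w)
    apd = apd + patch.apd_offset * w
    base_params = base_params or MMSParameters()
    if dx is None:
        dx = domain.spacing if domain.spacing is not None else 0.5
    return ParameterFieldSet.from_targets(cv, apd, base_params, dx=dx)


# ---------------------------------------------------------------------------
# virtual cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortCase:
    domain: TissueDomain
    fields: ParameterFieldSet
    record: CohortRecord
    true_mask: np.ndarray  # ground-truth substrate labels (bool per node)
    patch: SubstratePatchSpec


def _resolve_rule(tethering_rule):
    """Built-in ground-truth labelling rules for parameter-recovery tests."""
    if callable(tethering_rule):
        return tethering_rule
    if tethering_rule == "none":
        return lambda dom, f, rec, patch: np.zeros(dom.n_nodes, dtype=bool)
    if tethering_rule == "cv_patch":
        # substrate = the planted slow-CV patch core
        return lambda dom, f, rec, patch: patch_taper(dom, patch) > 0.5
    if tethering_rule == "cv_threshold":
        return lambda dom, f, rec, patch: f.cv_max < 100.0
    if tethering_rule == "cv_and_surface":
        # size threshold at the middle of the default cohort size range, so
        # the planted rule genuinely depends on atrial size
        return lambda dom, f, rec, patch: (f.cv_max < 100.0) & (rec.surface_cm2 > 350.0)
    raise ValueError(f"unknown tethering_rule: {tethering_rule!r}")


def make_virtual_cohort(
    n_cases: int,
    size_range: tuple[float, float] = (259.0, 440.0),
    tethering_rule="cv_patch",
    seed: int = 0,
    dx: float = 2.0,
    base_cv: float = 160.0,
    base_apd: float = 180.0,
    cv_scale_range: tuple[float, float] = (0.35, 0.5),
    apd_offset_range: tuple[float, float] = (-50.0, -20.0),
    patch_radius_range: tuple[float, float] = (12.0, 20.0),
    noise_sd: float = 0.05,
    base_params: MMSParameters | None = None,
    patch_center_box: tuple = (0.25, 0.75, 0.25, 0.75),
) -> list[CohortCase]:
    """A cohort of square-sheet cases spanning ``size_range`` cm**2, each
    with one planted substrate patch and a ground-truth mask from
    ``tethering_rule``.  Deterministic given ``seed``.

    Defaults mirror the observed contrast between substrate and healthy
    tissue: background CV_max around 160 cm/s with patches reaching
    ~60 cm/s, and substrate APD_max shortened by tens of ms.
    """
    if n_cases < 2:
        raise ValueError(f"n_cases must be >= 2, got {n_cases}")
    if not size_range[0] < size_range[1]:
        raise ValueError(f"degenerate size_range {size_range}: min must be < max")
    rule = _resolve_rule(tethering_rule)
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        area = rng.uniform(*size_range)  # cm^2
        side = np.sqrt(area * 100.0)     # mm
        nx = max(3, int(round(side / dx)) + 1)
        domain = make_sheet_domain(nx, nx, dx)
        lo, hi = domain.bounding_box()
        span = hi - lo
        radius = rng.uniform(*patch_radius_range)
        fx0, fx1, fy0, fy1 = patch_center_box
        center = (
            float(lo[0] + span[0] * rng.uniform(fx0, fx1)),
            float(lo[1] + span[1] * rng.uniform(fy0, fy1)),
        )
        patch = SubstratePatchSpec(
            center=center, radius=radius,
            cv_scale=float(rng.uniform(*cv_scale_range)),
            apd_offset=float(rng.uniform(*apd_offset_range)),
            correlation_length=10.0,
            cv_noise_sd=noise_sd, apd_noise_sd=noise_sd,
        )
        fields = sample_parameter_fields(
            domain, base_cv, base_apd, patch,
            seed=int(rng.integers(2**31)), base_params=base_params)
        record = CohortRecord(
            case_id=i + 1,
            age_years=float(np.clip(np.round(rng.normal(60.0, 12.0)), 30, 90)),
            sex="M" if rng.random() < 0.6 else "F",
            af_duration_years=float(np.round(rng.gamma(2.0, 1.3), 1)),
            af_class="PsAF" if rng.random() < 0.3 else "PAF",
            la_diameter_cm=float(np.round(rng.normal(3.8, 0.6), 1)),
            lvef_pct=float(np.round(rng.normal(60.0, 5.0))),
            surface_cm2=domain.total_surface,
        )
        mask = np.asarray(rule(domain, fields, record, patch), dtype=bool)
        cases.append(CohortCase(domain, fields, record, mask, patch))
    return cases


# ---------------------------------------------------------------------------
# virtual electrodes
# ---------------------------------------------------------------------------

def farthest_point_sites(domain: TissueDomain, n_sites: int, seed: int) -> np.ndarray:
    """Evenly spread node indices by farthest-point sampling, mimicking the
    roughly uniform spacing of clinical recording points."""
    rng = np.random.default_rng(seed)
    pos = domain.positions
    first = int(rng.integers(domain.n_nodes))
    chosen = [first]
    dmin = np.linalg.norm(pos - pos[first], axis=1)
    for _ in range(n_sites - 1):
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(pos - pos[nxt], axis=1))
    return np.asarray(chosen)


def synth_electrode_recordings(
    domain: TissueDomain,
    fields: ParameterFieldSet,
    n_sites: int = 14,
    noise_sd_ms: float = 0.0,
    seed: int = 0,
    s2_list=(300.0,),
    pacing_nodes=None,
    dt: float = 0.02,
    erp_resolution: float = 2.0,
) -> pd.DataFrame:
    """Sparse virtual-electrode table: LAT per S2 by forward simulation plus
    Gaussian noise, and the per-site refractory period from the single-cell
    S1-S2 capture threshold at the local parameters.

    Columns: site_id, x_mm, y_mm, z_mm, s2_ms, lat_ms, erp_ms.
    """
    from .monodomain_sim import run, s1s2_protocol, extract_lat  # avoid cycle

    if n_sites < 3:
        raise ValueError(f"n_sites must be >= 3, got {n_sites}")
    if n_sites > domain.n_nodes:
        raise ValueError(f"n_sites = {n_sites} exceeds node count {domain.n_nodes}")
    rng = np.random.default_rng(seed)
    sites = farthest_point_sites(domain, n_sites, seed=int(rng.integers(2**31)))
    if pacing_nodes is None:
        corner = domain.positions[:, :2].sum(axis=1)
        c = domain.positions[np.argmin(corner), :2]
        d = np.linalg.norm(domain.positions[:, :2] - c, axis=1)
        pacing_nodes = np.flatnonzero(d <= 2.0)
    lo, hi = domain.bounding_box()
    diag = float(np.linalg.norm(hi - lo))
    travel = diag / (fields.cv_max.min() / 100.0) + 60.0

    rows = []
    erp_cache: dict[int, float] = {}
    for s2 in sorted(s2_list):
        proto = s1s2_protocol(pacing_nodes, s1_count=1, s1_cl=s2 + travel, s2_couplings=[s2])
        hist = run(domain, fields, proto, duration=s2 + travel, dt=dt,
                   sample_interval=1.0)
        amap = extract_lat(hist, window=(s2, s2 + travel), t_ref=s2)
        noise = rng.normal(0.0, noise_sd_ms, size=n_sites) if noise_sd_ms > 0 else np.zeros(n_sites)
        for j, node in enumerate(sites):
            node = int(node)
            if node not in erp_cache:
                erp_cache[node] = erp_single_cell(
                    fields.local_parameters(node), dt=dt, resolution=erp_resolution)
            rows.append({
                "site_id": j,
                "x_mm": domain.positions[node, 0],
                "y_mm": domain.positions[node, 1],
                "z_mm": domain.positions[node, 2],
                "s2_ms": float(s2),
                "lat_ms": float(amap.lat[node] + noise[j]),
                "erp_ms": erp_cache[node],
            })
    table = pd.DataFrame(rows)
    table.attrs["pacing_nodes"] = [int(i) for i in np.atleast_1d(pacing_nodes)]
    return table


# ---------------------------------------------------------------------------
# packaged cohort table fixture
# ---------------------------------------------------------------------------

def load_cohort_table() -> list[CohortRecord]:
    """The packaged 10-case cohort-characteristics table."""
    with resources.files("rotortether.data").joinpath("cohort_characteristics.csv").open() as fh:
        df = pd.read_csv(fh)
    return [CohortRecord(**{k: row[k] for k in df.columns}) for _, row in df.iterrows()]


NUMERIC_COLUMNS = ["age_years", "af_duration_years", "la_diameter_cm",
                   "lvef_pct", "surface_cm2"]


def summarize_cohort(records: list[CohortRecord]) -> dict:
    """Column means and sample (n-1) SDs plus class fractions."""
    if len(records) < 2:
        raise ValueError("need at least 2 records to summarize")
    df = pd.DataFrame([vars(r) for r in records])
    out = {}
    for col in NUMERIC_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        out[col] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    out["paf_fraction"] = float((df["af_class"] == "PAF").mean())
    out["male_fraction"] = float((df["sex"] == "M").mean())
    return out
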