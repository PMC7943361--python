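"""Phase fields, phase-singularity detection, tracking, density maps, and
the tethering label.

Because both state variables of the mMS model are available in simulation,
the activation phase is taken directly in the (v, h) state plane as the
angle around a fixed origin inside the re-entry loop — no analytic-signal
(Hilbert) surrogate is needed.  A phase singularity (PS) is a point where
the phase winds by +/-2*pi around an elementary cell; it is detected by the
topological charge: the sum of wrapped phase differences around each
element's node loop.

The tethering label marks tissue whose time-aggregated PS density exceeds
the mean plus one standard deviation over nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tissue import TissueDomain, element_centroids, gaussian_smoothing_matrix
from .monodomain_sim import StateHistory

#: default phase origin in the (v, h) plane; inside the loop traced by a
#: re-entrant action potential
PHASE_ORIGIN = (0.5, 0.6)

PS_COLUMNS = ["t_ms", "x_mm", "y_mm", "z_mm", "chirality", "element", "track_id"]


def compute_phase(history: StateHistory, origin: tuple[float, float] = PHASE_ORIGIN,
                  check_origin: bool = True) -> np.ndarray:
    """State-plane phase theta = atan2(h - h*, v - v*), shape (n_samples,
    n_nodes), values in (-pi, pi].

    Warns if the observed (v, h) trajectory does not encircle the origin
    (all four quadrants visited), in which case PS detection is unreliable.
    """
    v0, h0 = origin
    dv = history.v.astype(np.float32) - np.float32(v0)
    dh = history.h.astype(np.float32) - np.float32(h0)
    if check_origin:
        quadrants = {(int(a), int(b)) for a, b in
                     zip((dv[:, ::17] > 0).ravel(), (dh[:, ::17] > 0).ravel())}
        if len(quadrants) < 4:
            warnings.warn(
                "phase origin lies outside the observed (v, h) loop; "
                "PS detection may be unreliable", stacklevel=2)
    return np.arctan2(dh, dv)


def _wrap(d):
    return (d + np.pi) % (2.0 * np.pi) - np.pi


def detect_ps(phase: np.ndarray, domain: TissueDomain, t_ms: float = 0.0) -> pd.DataFrame:
    """Phase singularities in one phase snapshot by topological charge.

    For every element the wrapped phase differences are summed around the
    node loop; a total of +/-2*pi marks a PS with that chirality, located at
    the element centroid.
    """
    elems = domain.elements
    loop = np.concatenate([elems, elems[:, :1]], axis=1)
    diffs = _wrap(np.diff(phase[loop], axis=1))
    charge = diffs.sum(axis=1) / (2.0 * np.pi)
    hit = np.abs(charge) > 0.5
    if not np.any(hit):
        return pd.DataFrame(columns=PS_COLUMNS)
    cent = element_centroids(domain)[hit]
    return pd.DataFrame({
        "t_ms": t_ms,
        "x_mm": cent[:, 0], "y_mm": cent[:, 1], "z_mm": cent[:, 2],
        "chirality": np.sign(charge[hit]).astype(int),
        "element": np.flatnonzero(hit),
        "track_id": -1,
    })


def detect_ps_history(history: StateHistory, domain: TissueDomain,
                      window: tuple[float, float] | None = None,
                      origin: tuple[float, float] = PHASE_ORIGIN) -> pd.DataFrame:
    """PS records for every sample in ``window`` (default: whole history)."""
    phase = compute_phase(history, origin)
    if window is None:
        window = (float(history.time[0]), float(history.time[-1]))
    sel = np.flatnonzero((history.time >= window[0]) & (history.time <= window[1]))
    frames = [detect_ps(phase[i], domain, t_ms=float(history.time[i])) for i in sel]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=PS_COLUMNS)
    return out


def boundary_winding(phase_snapshot: np.ndarray, domain: TissueDomain) -> int:
    """Winding number of the phase along the (sheet) domain boundary,
    counter-clockwise.  On a simply connected sheet this equals the net
    chirality of all interior singularities."""
    if domain.kind != "sheet":
        raise ValueError("boundary winding is defined for sheet domains")
    ny, nx = domain.shape
    idx = np.arange(domain.n_nodes).reshape(ny, nx)
    ring = np.concatenate([idx[0, :-1], idx[:-1, -1], idx[-1, :0:-1], idx[:0:-1, 0]])
    ring = np.append(ring, ring[0])
    total = _wrap(np.diff(phase_snapshot[ring])).sum()
    return int(np.round(total / (2.0 * np.pi)))


# ---------------------------------------------------------------------------
# track linking
# ---------------------------------------------------------------------------

def link_tracks(records: pd.DataFrame, max_jump: float = 5.0) -> pd.DataFrame:
    """Greedy nearest-neighbour linking of PS records into tracks.

    Successive samples are matched by ascending distance, requiring equal
    chirality and a jump of at most ``max_jump`` mm; unmatched singularities
    open new tracks.  Returns a copy with ``track_id`` assigned.
    """
    if records.empty:
        return records.copy()
    rec = records.sort_values("t_ms", kind="stable").reset_index(drop=True)
    rec["track_id"] = -1
    next_id = 0
    prev_idx: list[int] = []
    times = rec["t_ms"].to_numpy()
    xyz = rec[["x_mm", "y_mm", "z_mm"]].to_numpy()
    chir = rec["chirality"].to_numpy()
    tid = np.full(len(rec), -1, dtype=int)
    for t in np.unique(times):
        cur_idx = np.flatnonzero(times == t)
        if prev_idx:
            pi = np.asarray(prev_idx)
            d = np.linalg.norm(xyz[cur_idx][:, None, :] - xyz[pi][None, :, :], axis=2)
            same = chir[cur_idx][:, None] == chir[pi][None, :]
            d[~same] = np.inf
            pairs = sorted(
                ((d[a, b], a, b) for a in range(len(cur_idx)) for b in range(len(pi))
                 if d[a, b] <= max_jump),
                key=lambda z: z[0])
            used_a, used_b = set(), set()
            for _, a, b in pairs:
                if a in used_a or b in used_b:
                    continue
                tid[cur_idx[a]] = tid[pi[b]]
                used_a.add(a); used_b.add(b)
        for a, i in enumerate(cur_idx):
            if tid[i] < 0:
                tid[i] = next_id
                next_id += 1
        prev_idx = list(cur_idx)
    rec["track_id"] = tid
    return rec


def track_summary(linked: pd.DataFrame) -> pd.DataFrame:
    """Per-track birth/death times, dwell, and trajectory bounding radius."""
    if linked.empty:
        return pd.DataFrame(columns=["track_id", "t_birth", "t_death", "duration",
                                     "chirality", "radius", "n_samples"])
    rows = []
    for tid, g in linked.groupby("track_id"):
        xyz = g[["x_mm", "y_mm", "z_mm"]].to_numpy()
        center = xyz.mean(axis=0)
        rows.append({
            "track_id": tid,
            "t_birth": g["t_ms"].min(), "t_death": g["t_ms"].max(),
            "duration": g["t_ms"].max() - g["t_ms"].min(),
            "chirality": int(g["chirality"].iloc[0]),
            "radius": float(np.linalg.norm(xyz - center, axis=1).max()),
            "n_samples": len(g),
        })
    return pd.DataFrame(rows).sort_values("duration", ascending=False,
                                          ignore_index=True)


# ---------------------------------------------------------------------------
# density maps and the tethering label
# ---------------------------------------------------------------------------

@dataclass
class PSDensityMap:
    """Time-aggregated PS density per node, in PS * s / cm**2 scaled by the
    window (i.e. the time-average number of singularities per cm**2)."""
    density: np.ndarray
    window: tuple[float, float]
    smoothing_radius: float
    domain_nodes: int

    @property
    def total_mass(self) -> float:
        """Integral of density over the surface: mean PS count in the window."""
        return float(np.sum(self.density))  # see ps_density: stored per-node mass share


def ps_density(records: pd.DataFrame, domain: TissueDomain,
               window: tuple[float, float], sample_interval: float,
               smoothing_radius: float = 2.0) -> PSDensityMap:
    """Accumulate PS dwell time onto nodes and normalize to a density.

    Each PS record deposits ``sample_interval`` ms of dwell, split evenly
    over the nodes of its host element, then smeared by a mass-preserving
    Gaussian kernel.  The returned per-node values are
    dwell_mass / (node_area * window_length): the time-averaged number of
    singularities per cm**2.
    """
    t0, t1 = window
    if not t0 < t1:
        raise ValueError(f"empty aggregation window {window}")
    mass = np.zeros(domain.n_nodes)  # ms of PS dwell
    sel = records[(records["t_ms"] >= t0) & (records["t_ms"] <= t1)]
    if not sel.empty:
        elems = domain.elements[sel["element"].to_numpy(dtype=int)]
        share = sample_interval / elems.shape[1]
        np.add.at(mass, elems.ravel(), share)
    if smoothing_radius > 0 and mass.any():
        S = gaussian_smoothing_matrix(domain, smoothing_radius)
        mass = S.T @ mass
    area_cm2 = domain.node_area / 100.0
    density = mass / area_cm2 / (t1 - t0)
    return PSDensityMap(density=density, window=(t0, t1),
                        smoothing_radius=smoothing_radius,
                        domain_nodes=domain.n_nodes)


def density_mass(dmap: PSDensityMap, domain: TissueDomain) -> float:
    """Surface integral of the density times the window length, in ms of PS
    dwell; equals (number of PS records) * sample_interval exactly."""
    area_cm2 = domain.node_area / 100.0
    return float(np.sum(dmap.density * area_cm2) * (dmap.window[1] - dmap.window[0]))


@dataclass
class TetheringLabelField:
    """Boolean per-node substrate mask: density strictly above mean + 1 SD."""
    label: np.ndarray
    threshold: float
    mean: float
    sd: float
    area_weighted: bool = False


def tethering_mask(dmap: PSDensityMap, domain: TissueDomain | None = None,
                   area_weighted: bool = False) -> TetheringLabelField:
    """Label nodes whose PS density exceeds mean + 1 standard deviation.

    The SD is the sample (n-1) standard deviation over nodes; an
    area-weighted variant is available when nodes carry unequal areas.
    """
    d = dmap.density
    if area_weighted:
        if domain is None:
            raise ValueError("area_weighted thresholding needs the domain")
        w = domain.node_area / domain.node_area.sum()
        mean = float(np.sum(w * d))
        var = float(np.sum(w * (d - mean) ** 2) / (1.0 - np.sum(w ** 2)))
        sd = var ** 0.5
    else:
        mean = float(np.mean(d))
        sd = float(np.std(d, ddof=1))
    thr = mean + sd
    return TetheringLabelField(label=d > thr, threshold=thr, mean=mean, sd=sd,
                               area_weighted=area_weighted)


def combine_maps(maps: list[PSDensityMap]):
    """Nodewise sum of density maps sharing a domain, plus the pairwise
    cosine dissimilarity matrix quantifying how different the maps are."""
    if not maps:
        raise ValueError("no maps to combine")
    n = maps[0].domain_nodes
    if any(m.domain_nodes != n for m in maps):
        raise ValueError("density maps live on different domains")
    stack = np.stack([m.density for m in maps])
    combined = PSDensityMap(density=stack.sum(axis=0),
                            window=(min(m.window[0] for m in maps),
                                    max(m.window[1] for m in maps)),
                            smoothing_radius=maps[0].smoothing_radius,
                            domain_nodes=n)
    norms = np.linalg.norm(stack, axis=1)
    k = len(maps)
    dis = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if norms[i] == 0 or norms[j] == 0:
                dis[i, j] = 1.0
            else:
                dis[i, j] = 1.0 - float(stack[i] @ stack[j]) / (norms[i] * norms[j])
    return combined, dis
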