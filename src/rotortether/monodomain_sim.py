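"""Monodomain reaction-diffusion solver on sheets and surface meshes.

The transmembrane variable obeys dv/dt = div(D grad v) + I_ion(v, h) + I_stim
with heterogeneous per-node conductivity D and the mMS reaction from
:mod:`rotortether.mms_model`.  Spatial discretization is a 5-point finite
difference stencil on sheets and a mass-lumped linear-FEM cotangent Laplacian
on triangle meshes; in both cases the conductivity on an edge is the harmonic
mean of the two nodal values, which preserves wave-speed behaviour across
parameter gradients.  Time stepping is forward Euler with operator splitting;
the step is validated against the explicit stability bound before any work is
done.  Boundaries are zero-flux.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .mms_model import V_THR, ParameterFieldSet
from .tissue import TissueDomain

try:  # fused stepping kernel; the numpy path below is the reference
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

#: marker for nodes that never activate in a window
NOT_ACTIVATED = np.nan


# ---------------------------------------------------------------------------
# stimulus protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pulse:
    """One rectangular stimulus: an additive source on dv/dt (ms^-1) applied
    to a node set for ``duration`` ms starting at ``start`` ms."""
    nodes: tuple
    start: float
    duration: float
    amplitude: float = 1.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"pulse duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class StimulusProtocol:
    kind: str                 # "single" | "S1S2" | "burst" | "cross-field"
    pulses: tuple             # tuple of Pulse
    meta: str = ""

    @property
    def end_time(self) -> float:
        return max(p.start + p.duration for p in self.pulses)

    def describe(self) -> str:
        return json.dumps({
            "kind": self.kind,
            "meta": self.meta,
            "pulses": [[len(p.nodes), p.start, p.duration, p.amplitude]
                       for p in self.pulses],
        })


def single_pulse(nodes, start: float = 0.0, duration: float = 2.0,
                 amplitude: float = 1.0) -> StimulusProtocol:
    return StimulusProtocol("single",
                            (Pulse(tuple(int(i) for i in nodes), start, duration, amplitude),))


def s1s2_protocol(nodes, s1_count: int, s1_cl: float, s2_couplings,
                  start: float = 0.0, duration: float = 2.0,
                  amplitude: float = 1.0) -> StimulusProtocol:
    """S1 train at cycle length ``s1_cl`` followed by premature S2 stimuli at
    the given coupling intervals after the last S1."""
    if s1_count < 1:
        raise ValueError("s1_count must be >= 1")
    s2_couplings = tuple(float(c) for c in np.atleast_1d(s2_couplings))
    if any(c >= s1_cl for c in s2_couplings):
        raise ValueError("S2 coupling intervals must be shorter than the S1 cycle length")
    nodes = tuple(int(i) for i in nodes)
    pulses = [Pulse(nodes, start + k * s1_cl, duration, amplitude)
              for k in range(s1_count)]
    last = start + (s1_count - 1) * s1_cl
    t = last
    for c in s2_couplings:
        t = t + c
        pulses.append(Pulse(nodes, t, duration, amplitude))
    return StimulusProtocol("S1S2", tuple(pulses),
                            meta=f"s1_cl={s1_cl},s2={list(s2_couplings)}")


def burst_protocol(nodes, n_beats: int = 20, cycle_length: float = 130.0,
                   start: float = 0.0, duration: float = 2.0,
                   amplitude: float = 1.0) -> StimulusProtocol:
    """Rapid pacing train used to induce re-entry."""
    if n_beats < 1:
        raise ValueError("burst beat count must be >= 1")
    nodes = tuple(int(i) for i in nodes)
    pulses = tuple(Pulse(nodes, start + k * cycle_length, duration, amplitude)
                   for k in range(n_beats))
    return StimulusProtocol("burst", pulses,
                            meta=f"cl={cycle_length},n={n_beats}")


def cross_field_protocol(domain: TissueDomain, s2_time: float,
                         duration: float = 2.0,
                         amplitude: float = 1.0) -> StimulusProtocol:
    """Classic spiral-initiation construction on a sheet: an S1 plane wave
    from the left edge, then an S2 over the lower half while the S1
    repolarization tail crosses the sheet."""
    if domain.kind != "sheet":
        raise ValueError("cross-field protocol requires a sheet domain")
    ny, nx = domain.shape
    idx = np.arange(domain.n_nodes)
    left = idx[idx % nx < 2]
    lower = idx[(idx // nx) < ny // 2]
    return StimulusProtocol(
        "cross-field",
        (Pulse(tuple(int(i) for i in left), 0.0, duration, amplitude),
         Pulse(tuple(int(i) for i in lower), s2_time, duration, amplitude)),
        meta=f"s2={s2_time}",
    )


# ---------------------------------------------------------------------------
# state history
# ---------------------------------------------------------------------------

@dataclass
class StateHistory:
    """Sampled (v, h) fields.  ``v`` and ``h`` are (n_samples, n_nodes)
    float32 arrays; ``time`` is in ms."""
    time: np.ndarray
    v: np.ndarray
    h: np.ndarray
    dt: float
    sample_interval: float
    protocol: str = ""

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.v.shape[1]

    @property
    def end_time(self) -> float:
        return float(self.time[-1])


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def _harmonic(a, b):
    return 2.0 * a * b / (a + b)


def build_laplacian(domain: TissueDomain, diffusivity: np.ndarray) -> sparse.csr_matrix:
    """Weighted Laplacian L (units ms^-1 when applied to v) with zero-flux
    boundaries and harmonic-mean edge conductivities."""
    D = np.asarray(diffusivity, dtype=float)
    if np.any(D <= 0):
        raise ValueError("diffusivity must be strictly positive everywhere")
    n = domain.n_nodes
    if domain.kind == "sheet":
        ny, nx = domain.shape
        dx = domain.spacing
        idx = np.arange(n).reshape(ny, nx)
        pairs = np.concatenate([
            np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()]),
            np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()]),
        ])
        w = _harmonic(D[pairs[:, 0]], D[pairs[:, 1]]) / (dx * dx)
    else:
        tris = domain.elements
        p = domain.positions
        # cotangent weights: for each triangle corner, the half-cot of its
        # angle weights the opposite edge
        ii, jj, ww = [], [], []
        for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
            u = p[tris[:, a]] - p[tris[:, c]]
            v = p[tris[:, b]] - p[tris[:, c]]
            cos = np.sum(u * v, axis=1)
            sin = np.linalg.norm(np.cross(u, v), axis=1)
            cot = cos / np.maximum(sin, 1e-12)
            ii.append(tris[:, a]); jj.append(tris[:, b]); ww.append(0.5 * cot)
        pairs = np.column_stack([np.concatenate(ii), np.concatenate(jj)])
        cotw = np.concatenate(ww)
        # accumulate duplicate edges (the two adjacent triangles)
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs, cotw = pairs[order], cotw[order]
        w = cotw * _harmonic(D[pairs[:, 0]], D[pairs[:, 1]])
        # geometric weight is symmetric per undirected edge; mass lumping below
        w = w / 1.0
        mass = domain.node_area
        mat = sparse.csr_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([pairs[:, 0], pairs[:, 1]]),
              np.concatenate([pairs[:, 1], pairs[:, 0]]))),
            shape=(n, n))
        mat = mat - sparse.diags(np.asarray(mat.sum(axis=1)).ravel())
        return (sparse.diags(1.0 / mass) @ mat).tocsr()
    mat = sparse.csr_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([pairs[:, 0], pairs[:, 1]]),
          np.concatenate([pairs[:, 1], pairs[:, 0]]))),
        shape=(n, n))
    mat = mat - sparse.diags(np.asarray(mat.sum(axis=1)).ravel())
    return mat.tocsr()


def stability_limit(L: sparse.csr_matrix, tau_in_min: float) -> float:
    """Largest forward-Euler time step: Gershgorin bound on the diffusion
    operator combined with the reaction bound dt <= 0.1 * tau_in."""
    diag_max = float(np.abs(L.diagonal()).max())
    dt_diff = 1.0 / diag_max if diag_max > 0 else np.inf
    return min(dt_diff, 0.1 * tau_in_min)


# ---------------------------------------------------------------------------
# the solver
# ---------------------------------------------------------------------------

def _step_block_numpy(v, h, L, vg, inv_tin, inv_tout, inv_topen, inv_tclose,
                      dt, t_start, n_steps, pulse_ptr, pulse_nodes,
                      pulse_t0, pulse_t1, pulse_amp):
    for s in range(n_steps):
        t = t_start + s * dt
        dv = L @ v
        dv += h * v * (v - vg) * (1.0 - v) * inv_tin
        dv -= v * inv_tout
        for pp in range(pulse_t0.shape[0]):
            if pulse_t0[pp] <= t < pulse_t1[pp]:
                dv[pulse_nodes[pulse_ptr[pp]:pulse_ptr[pp + 1]]] += pulse_amp[pp]
        h += dt * np.where(v < vg, (1.0 - h) * inv_topen, -h * inv_tclose)
        v += dt * dv


if _HAVE_NUMBA:
    @_njit(cache=True)
    def _step_block_csr(v, h, indptr, indices, data, vg, inv_tin, inv_tout,
                        inv_topen, inv_tclose, dt, t_start, n_steps,
                        pulse_ptr, pulse_nodes, pulse_t0, pulse_t1, pulse_amp):
        n = v.shape[0]
        dv = np.empty(n)
        for s in range(n_steps):
            t = t_start + s * dt
            for i in range(n):
                acc = 0.0
                for k in range(indptr[i], indptr[i + 1]):
                    acc += data[k] * v[indices[k]]
                vi = v[i]
                acc += h[i] * vi * (vi - vg[i]) * (1.0 - vi) * inv_tin[i]
                acc -= vi * inv_tout[i]
                dv[i] = acc
            for pp in range(pulse_t0.shape[0]):
                if pulse_t0[pp] <= t < pulse_t1[pp]:
                    for q in range(pulse_ptr[pp], pulse_ptr[pp + 1]):
                        dv[pulse_nodes[q]] += pulse_amp[pp]
            for i in range(n):
                if v[i] < vg[i]:
                    h[i] += dt * (1.0 - h[i]) * inv_topen[i]
                else:
                    h[i] -= dt * h[i] * inv_tclose[i]
                v[i] += dt * dv[i]


def run(
    domain: TissueDomain,
    fields: ParameterFieldSet,
    protocol: StimulusProtocol,
    duration: float,
    dt: float = 0.02,
    sample_interval: float = 1.0,
    initial: tuple[np.ndarray, np.ndarray] | None = None,
) -> StateHistory:
    """Integrate the monodomain equations and return the sampled history.

    Deterministic: identical inputs give bit-identical histories.  Raises
    before integrating if ``dt`` violates the explicit stability bound, and
    aborts with the failure time if the state ever becomes non-finite.
    """
    if fields.n_nodes != domain.n_nodes:
        raise ValueError("fields and domain disagree on node count")
    if duration < protocol.end_time:
        raise ValueError(
            f"duration {duration} ms ends before the protocol ({protocol.end_time} ms)")
    L = build_laplacian(domain, fields.diffusivity)
    dt_max = stability_limit(L, float(fields.tau_in.min()))
    if dt > dt_max + 1e-12:
        raise ValueError(
            f"dt = {dt} ms violates the stability bound {dt_max:.4f} ms "
            f"for this domain and conductivity")
    k = int(round(sample_interval / dt))
    if abs(k * dt - sample_interval) > 1e-9:
        raise ValueError("sample_interval must be an integer multiple of dt")

    n = domain.n_nodes
    if initial is not None:
        v = np.array(initial[0], dtype=float)
        h = np.array(initial[1], dtype=float)
    else:
        v = np.zeros(n)
        h = np.ones(n)

    inv_tin = 1.0 / fields.tau_in
    inv_tout = 1.0 / fields.tau_out
    inv_topen = 1.0 / fields.tau_open
    inv_tclose = 1.0 / fields.tau_close
    vg = fields.v_gate

    pulse_nodes = np.concatenate(
        [np.fromiter(p.nodes, dtype=np.int64) for p in protocol.pulses])
    pulse_ptr = np.cumsum([0] + [len(p.nodes) for p in protocol.pulses]).astype(np.int64)
    pulse_t0 = np.array([p.start for p in protocol.pulses])
    pulse_t1 = np.array([p.start + p.duration for p in protocol.pulses])
    pulse_amp = np.array([p.amplitude for p in protocol.pulses])

    n_steps = int(round(duration / dt))
    n_samp = n_steps // k + 1
    vout = np.empty((n_samp, n), dtype=np.float32)
    hout = np.empty((n_samp, n), dtype=np.float32)
    vout[0], hout[0] = v, h
    for isamp in range(1, n_samp):
        t_start = (isamp - 1) * k * dt
        if _HAVE_NUMBA:
            _step_block_csr(v, h, L.indptr, L.indices, L.data, vg,
                            inv_tin, inv_tout, inv_topen, inv_tclose,
                            dt, t_start, k, pulse_ptr, pulse_nodes,
                            pulse_t0, pulse_t1, pulse_amp)
        else:
            _step_block_numpy(v, h, L, vg, inv_tin, inv_tout, inv_topen,
                              inv_tclose, dt, t_start, k, pulse_ptr,
                              pulse_nodes, pulse_t0, pulse_t1, pulse_amp)
        if not np.isfinite(v[0]) or not np.all(np.isfinite(v)):
            raise FloatingPointError(
                f"non-finite state at t = {isamp * k * dt:.2f} ms")
        # flush the exponential decay toward rest to rest exactly: subnormal
        # v (or 1-h) values otherwise stall the floating-point units
        np.copyto(v, 0.0, where=np.abs(v) < 1e-30)
        np.copyto(h, 1.0, where=np.abs(h - 1.0) < 1e-30)
        vout[isamp], hout[isamp] = v, h
    time = np.arange(n_samp) * sample_interval
    return StateHistory(time=time, v=vout, h=hout, dt=dt,
                        sample_interval=sample_interval,
                        protocol=protocol.describe())


# ---------------------------------------------------------------------------
# activation maps and refractoriness
# ---------------------------------------------------------------------------

@dataclass
class ActivationMap:
    """Per-node local activation times (ms, relative to ``t_ref``);
    non-activated nodes carry the NaN marker."""
    lat: np.ndarray
    t_ref: float
    v_thr: float
    window: tuple[float, float]

    @property
    def activated(self) -> np.ndarray:
        return np.isfinite(self.lat)


def extract_lat(history: StateHistory, v_thr: float = V_THR,
                window: tuple[float, float] | None = None,
                t_ref: float | None = None) -> ActivationMap:
    """First upward crossing of ``v_thr`` per node inside ``window``,
    linearly interpolated between samples.

    The window must contain exactly one paced beat; a second upstroke at any
    node is rejected.
    """
    if window is None:
        window = (float(history.time[0]), float(history.time[-1]))
    t0, t1 = window
    sel = (history.time >= t0) & (history.time <= t1)
    if sel.sum() < 2:
        raise ValueError(f"window {window} contains fewer than two samples")
    t = history.time[sel]
    v = history.v[sel].astype(float)
    below = v[:-1] < v_thr
    above = v[1:] >= v_thr
    crossings = below & above  # (S-1, n)
    n_cross = crossings.sum(axis=0)
    if np.any(n_cross > 1):
        raise ValueError(
            f"window {window} contains more than one beat at "
            f"{int((n_cross > 1).sum())} node(s)")
    lat = np.full(history.n_nodes, NOT_ACTIVATED)
    rows, cols = np.nonzero(crossings)
    frac = (v_thr - v[rows, cols]) / (v[rows + 1, cols] - v[rows, cols])
    if t_ref is None:
        t_ref = t0
    lat[cols] = t[rows] + frac * (t[rows + 1] - t[rows]) - t_ref
    return ActivationMap(lat=lat, t_ref=float(t_ref), v_thr=v_thr, window=(t0, t1))


#: sentinel results for measure_erp
ERP_BELOW_GRID = "below-grid"
ERP_ABOVE_GRID = "above-grid"


def measure_erp(
    domain: TissueDomain,
    fields: ParameterFieldSet,
    site,
    s1_count: int = 3,
    s1_cl: float = 500.0,
    s2_grid=None,
    capture_radius: float = 5.0,
    dt: float = 0.02,
    v_thr: float = V_THR,
):
    """Tissue-level ERP at a pacing site by bisection over an S2 grid.

    The S1 train is run once and its final state reused for every S2 probe.
    Capture means a propagated response: some node farther than
    ``capture_radius`` mm from the site activates after the S2.  Returns the
    longest failing S2, or the ``ERP_BELOW_GRID`` / ``ERP_ABOVE_GRID``
    markers when the grid does not bracket the threshold.
    """
    s2_grid = np.asarray(
        s2_grid if s2_grid is not None else np.arange(80.0, 400.0, 5.0), dtype=float)
    if np.any(np.diff(s2_grid) <= 0):
        raise ValueError("S2 grid must be sorted strictly ascending")
    site = np.fromiter((int(i) for i in np.atleast_1d(site)), dtype=np.int64)
    center = domain.positions[site].mean(axis=0)
    dist = np.linalg.norm(domain.positions - center, axis=1)
    band = (dist > capture_radius) & (dist <= 2.0 * capture_radius)
    if not np.any(band):
        band = dist > capture_radius

    # run the first s1_count-1 conditioning beats once; every S2 probe then
    # restarts from that state with the final S1 at t = 0
    if s1_count > 1:
        t_snap = (s1_count - 1) * s1_cl
        pre = run(domain, fields, burst_protocol(site, s1_count - 1, s1_cl),
                  duration=t_snap, dt=dt, sample_interval=1.0)
        init0 = (pre.v[-1].astype(float), pre.h[-1].astype(float))
    else:
        init0 = None

    def captures(s2: float) -> bool:
        proto = StimulusProtocol(
            "S1S2", (Pulse(tuple(int(i) for i in site), 0.0, 2.0),
                     Pulse(tuple(int(i) for i in site), s2, 2.0)))
        hist = run(domain, fields, proto, duration=s2 + 80.0, dt=dt,
                   sample_interval=1.0, initial=init0)
        # capture = a propagated response on the S2 beat only: a fresh
        # upstroke in the band after the S2 was delivered
        sel = hist.time >= s2
        vb = hist.v[sel][:, band].astype(float)
        return bool(np.any((vb[:-1] < v_thr) & (vb[1:] >= v_thr)))

    lo_i, hi_i = 0, len(s2_grid) - 1
    if captures(s2_grid[lo_i]):
        return ERP_BELOW_GRID
    if not captures(s2_grid[hi_i]):
        return ERP_ABOVE_GRID
    while hi_i - lo_i > 1:
        mid = (lo_i + hi_i) // 2
        if captures(s2_grid[mid]):
            hi_i = mid
        else:
            lo_i = mid
    return float(s2_grid[lo_i])


# ---------------------------------------------------------------------------
# pacing sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PacingSite:
    site_id: int
    zone: str
    nodes: tuple


def make_pacing_sites(domain: TissueDomain, scheme: str = "four-corner-zones",
                      site_radius: float = 1.5) -> list[PacingSite]:
    """Twelve pacing sites in four zones of three.

    On sheets the four corner zones stand in for the four pulmonary veins;
    each zone holds three sites placed along its inner diagonal.  On meshes
    zones are seeded from the four bounding-box corners.
    """
    if scheme not in ("four-corner-zones", "labelled-PV-zones"):
        raise ValueError(f"unknown pacing scheme: {scheme}")
    lo, hi = domain.bounding_box()
    span = hi - lo
    if min(span[0], span[1]) < 12 * site_radius:
        raise ValueError("domain too small to place 12 disjoint pacing sites")
    zones = {
        "LSPV": (0.15, 0.85), "LIPV": (0.15, 0.15),
        "RSPV": (0.85, 0.85), "RIPV": (0.85, 0.15),
    }
    sites = []
    sid = 0
    for zone, (fx, fy) in zones.items():
        cx = lo[0] + fx * span[0]
        cy = lo[1] + fy * span[1]
        toward = np.sign([0.5 - fx, 0.5 - fy])
        for k in (-1, 0, 1):
            px = cx + toward[0] * k * 4.0 * site_radius
            py = cy + toward[1] * k * 4.0 * site_radius
            d = np.linalg.norm(domain.positions[:, :2] - [px, py], axis=1)
            nodes = np.flatnonzero(d <= site_radius)
            if nodes.size == 0:
                nodes = np.array([int(np.argmin(d))])
            sites.append(PacingSite(sid, zone, tuple(int(i) for i in nodes)))
            sid += 1
    # disjointness guarantee
    seen = set()
    for s in sites:
        if seen & set(s.nodes):
            raise ValueError("pacing sites overlap; domain too small")
        seen |= set(s.nodes)
    return sites
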