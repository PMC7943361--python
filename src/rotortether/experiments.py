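"""Canonical desk-scale experiments.

These bundle the standard small-sheet constructions used throughout the
test-bench analyses: a cross-field-initiated spiral on a 5 x 5 cm sheet,
and the planted-substrate localization experiment in which a slow-CV /
short-APD patch is expected to tether the rotor so that the derived
tethering mask sits on the patch.

The tissue operating point (CV_max 30 cm/s, APD_max 80 ms, tau_open 65 ms)
is a diseased-atrium regime whose wavelength (~2.4 cm) fits the 5 cm sheet,
so a single re-entrant rotor is sustainable; clinical-scale speeds around
160 cm/s need the full atrial surface to accommodate a wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mms_model import MMSParameters
from .monodomain_sim import StateHistory, cross_field_protocol, run
from .phase_mapping import (detect_ps_history, link_tracks, ps_density,
                            tethering_mask, track_summary)
from .synthetic_cohort import SubstratePatchSpec, sample_parameter_fields
from .tissue import TissueDomain, make_sheet_domain

#: cell-model operating point for the desk-scale spiral experiments
SPIRAL_BASE = MMSParameters(tau_open=65.0)
SPIRAL_CV = 30.0      # cm/s
SPIRAL_APD = 80.0     # ms
SPIRAL_S2_MS = 167.0  # cross-field S2: one sheet-crossing time after S1


def spiral_sheet(nx: int = 101, dx: float = 0.5) -> TissueDomain:
    return make_sheet_domain(nx, nx, dx)


def run_spiral(
    domain: TissueDomain | None = None,
    patch: SubstratePatchSpec | None = None,
    seed: int = 0,
    duration: float = 2000.0,
    dt: float = 0.025,
    sample_interval: float = 2.5,
    s2_time: float = SPIRAL_S2_MS,
) -> tuple[TissueDomain, StateHistory]:
    """Cross-field-initiated spiral; uniform tissue unless a patch is given."""
    domain = domain or spiral_sheet()
    if patch is None:
        patch = SubstratePatchSpec(center=(0.0, 0.0), radius=1.0)  # identity
    fields = sample_parameter_fields(
        domain, SPIRAL_CV, SPIRAL_APD, patch, seed=seed, base_params=SPIRAL_BASE)
    hist = run(domain, fields, cross_field_protocol(domain, s2_time),
               duration=duration, dt=dt, sample_interval=sample_interval)
    return domain, hist


@dataclass
class LocalizationResult:
    seed: int
    sustained: bool
    mask_nodes: int
    centroid: tuple[float, float] | None
    centroid_in_patch: bool
    patch: SubstratePatchSpec


def planted_substrate_localization(
    seed: int,
    cv_scale: float = 0.5,
    apd_offset: float = -20.0,
    patch_radius: float = 10.0,
    noise_sd: float = 0.05,
    duration: float = 2000.0,
) -> LocalizationResult:
    """One seeded trial of the substrate-localization experiment.

    A slow-CV patch (scaled by ``cv_scale``) is planted at a seeded position
    in the central region of the sheet; a cross-field spiral is initiated,
    the PS density over the second half of the run is aggregated, and the
    trial succeeds if the tethering mask's density-weighted centroid falls
    inside the patch.
    """
    rng = np.random.default_rng(seed)
    domain = spiral_sheet()
    lo, hi = domain.bounding_box()
    span = hi - lo
    center = (float(lo[0] + span[0] * rng.uniform(0.35, 0.65)),
              float(lo[1] + span[1] * rng.uniform(0.35, 0.65)))
    patch = SubstratePatchSpec(
        center=center, radius=patch_radius, cv_scale=cv_scale,
        apd_offset=apd_offset, correlation_length=8.0,
        cv_noise_sd=noise_sd, apd_noise_sd=noise_sd)
    _, hist = run_spiral(domain, patch, seed=int(rng.integers(2**31)),
                         duration=duration)
    window = (duration / 2.0, duration)
    active = (hist.v > 0.1).any(axis=1)
    sustained = bool(active[hist.time >= duration - 2 * hist.sample_interval].any())
    rec = detect_ps_history(hist, domain, window=window)
    dmap = ps_density(rec, domain, window, sample_interval=hist.sample_interval)
    mask = tethering_mask(dmap)
    if mask.label.sum() == 0:
        return LocalizationResult(seed, sustained, 0, None, False, patch)
    w = dmap.density * mask.label
    cx, cy = (float(np.average(domain.positions[:, 0], weights=w)),
              float(np.average(domain.positions[:, 1], weights=w)))
    inside = np.hypot(cx - center[0], cy - center[1]) <= patch_radius
    return LocalizationResult(seed, sustained, int(mask.label.sum()),
                              (cx, cy), bool(inside), patch)


def spiral_track_report(domain: TissueDomain, hist: StateHistory,
                        window: tuple[float, float]):
    """Linked PS tracks plus summary for a spiral run (analysis window)."""
    rec = detect_ps_history(hist, domain, window=window)
    linked = link_tracks(rec)
    return linked, track_summary(linked)
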