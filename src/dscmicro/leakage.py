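"""Apparent blood-brain-barrier leakage (K_app) estimation.

A leaking voxel's gradient-echo relaxation curve deviates from a
non-leaky reference by a term proportional to the cumulative amount of
contrast that has passed: the canonical two-regressor linear model

    dR2*_voxel(t) ~= k1 * dR2*_ref(t) - kapp * integral_0^t dR2*_ref(tau) dtau

where the reference is the mean curve over screened normal-appearing
white matter.  kapp (1/s) is signed: positive kapp depresses the late
tail of the curve relative to the intravascular reference, negative kapp
elevates it; the magnitude quantifies barrier permeability in either
regime.  The regressor basis is pluggable (see ``estimate_kapp``'s
``from_residue`` path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from dscmicro.curves import ConcentrationCurve
from dscmicro.synthgen import DynamicStudy
from dscmicro.kinetics import signal_to_delta_r2, ArterialInputFunction, deconvolve_svd


@dataclass
class LeakageParams:
    """Two-regressor leakage fit for one voxel."""

    k1: float      # unitless scale vs reference
    kapp: float    # 1/s, signed
    r2: float      # coefficient of determination of the fit


def build_reference_curve(
    study: DynamicStudy,
    nawm_mask: np.ndarray,
    *,
    bolus_gate_sd: float = 3.0,
    tail_slope_frac: float = 0.05,
    tail_offset_frac: float = 0.025,
    min_voxels: int = 10,
    clamp: bool = True,
) -> ConcentrationCurve:
    """Mean non-leaky NAWM relaxation curve for leakage regression.

    Mask voxels qualify when they show a clear bolus (peak above
    ``bolus_gate_sd`` baseline SDs, with an absolute floor for noiseless
    data) and a non-leaky post-bolus tail, screened two ways over the
    last quarter of the series: the linear trend must stay below
    ``tail_slope_frac`` of the peak per minute, and the tail must return
    to baseline — its mean must stay within ``tail_offset_frac`` of the
    peak.  The offset screen is the sensitive one: extravasation mostly
    accrues during bolus passage, so a leaky curve plateaus at a shifted
    baseline rather than continuing to drift.
    """
    if not np.any(nawm_mask):
        raise ValueError("empty NAWM mask")
    protocol = study.protocol
    bf = protocol.baseline_frames
    t = protocol.times
    curves = []
    for idx in np.argwhere(nawm_mask):
        idx = tuple(idx)
        try:
            conc = signal_to_delta_r2(
                study.signal_gre[idx], protocol.te_gre, bf, t, clamp=clamp
            )
        except ValueError:
            continue
        v = conc.values
        base_sd = float(v[:bf].std())
        peak = float(v.max())
        if peak <= max(bolus_gate_sd * base_sd, 1e-9):
            continue
        tail = v[-(v.size // 4):]
        tail_t = t[-(v.size // 4):]
        slope = float(np.polyfit(tail_t, tail, 1)[0])  # 1/s per second
        if abs(slope) * 60.0 > tail_slope_frac * peak:
            continue
        if abs(float(tail.mean())) > tail_offset_frac * peak:
            continue
        curves.append(v)
    if len(curves) < min_voxels:
        raise ValueError(
            f"only {len(curves)} voxels passed the non-leaky screen "
            f"(need {min_voxels}); widen the mask or relax the screen"
        )
    return ConcentrationCurve(np.mean(curves, axis=0), t, echo="GRE")


def estimate_kapp(
    voxel: ConcentrationCurve,
    reference: ConcentrationCurve,
) -> LeakageParams:
    """Regress a voxel curve on the reference and its cumulative integral.

    Ordinary least squares for (k1, kapp) in
    ``voxel = k1*ref - kapp*cumint(ref)``; the estimator is linear in the
    voxel curve, so injected leakage is recovered exactly (noiseless) and
    flipping its sign flips only the sign of kapp.
    """
    if not voxel.same_timebase(reference):
        raise ValueError("voxel and reference must share a timebase")
    ref = reference.values
    if not np.any(ref != 0):
        raise ValueError("reference curve is identically zero")
    cum = cumulative_trapezoid(ref, reference.times, initial=0.0)
    x = np.column_stack([ref, -cum])
    coef, *_ = np.linalg.lstsq(x, voxel.values, rcond=None)
    fitted = x @ coef
    ss_res = float(np.sum((voxel.values - fitted) ** 2))
    ss_tot = float(np.sum((voxel.values - voxel.values.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LeakageParams(k1=float(coef[0]), kapp=float(coef[1]),
                         r2=float(np.clip(r2, 0.0, 1.0)))


def estimate_kapp_from_residue(
    voxel: ConcentrationCurve,
    reference: ConcentrationCurve,
    aif: ArterialInputFunction | ConcentrationCurve,
    *,
    threshold: float = 0.1,
) -> LeakageParams:
    """Alternative regressor basis built from deconvolved residue functions.

    Both the voxel and reference curves are deconvolved by the AIF first,
    and the two-regressor model is applied to the flow-scaled residues.
    Useful when bolus delay/dispersion differs between voxel and
    reference; the raw-curve regression remains the default.
    """
    ev = deconvolve_svd(voxel, aif, threshold=threshold)
    er = deconvolve_svd(reference, aif, threshold=threshold)
    # flow-scaled residues (cbf/60 * R) retain the relative voxel scale
    rv = ev.residue * ev.cbf / 60.0
    rr = er.residue * er.cbf / 60.0
    t = voxel.times
    return estimate_kapp(
        ConcentrationCurve(rv, t, echo=voxel.echo),
        ConcentrationCurve(rr, t, echo=reference.echo),
    )


def kapp_map(
    study: DynamicStudy,
    nawm_mask: np.ndarray,
    analysis_mask: np.ndarray | None = None,
    *,
    reference_summary: float | None = None,
    clamp: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Voxel-wise K_app map, plus a relative map when a reference summary
    (e.g. the nine-ROI NAWM mean from roi_stats) is supplied.

    Returns ``(kapp, relative_kapp)``; voxels outside the analysis mask or
    with unusable signal are NaN.  Deterministic for fixed inputs.
    """
    reference = build_reference_curve(study, nawm_mask, clamp=clamp)
    protocol = study.protocol
    shape = study.shape
    if analysis_mask is None:
        analysis_mask = np.ones(shape, dtype=bool)
    out = np.full(shape, np.nan)
    for idx in np.argwhere(analysis_mask):
        idx = tuple(idx)
        try:
            conc = signal_to_delta_r2(
                study.signal_gre[idx], protocol.te_gre,
                protocol.baseline_frames, protocol.times, clamp=clamp,
            )
        except ValueError:
            continue
        out[idx] = estimate_kapp(conc, reference).kapp
    rel = None
    if reference_summary is not None:
        if reference_summary <= 0:
            raise ValueError("reference summary must be positive")
        rel = out / reference_summary
    return out, rel
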