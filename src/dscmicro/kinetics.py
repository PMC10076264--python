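"""Signal-to-relaxation conversion, gamma-variate fits, AIF selection and
SVD deconvolution for nonparametric perfusion (CBF/CBV/MTT)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import svd as _svd

from dscmicro.protocol import AcquisitionProtocol
from dscmicro.curves import ConcentrationCurve, SignalTimeSeries, gamma_variate
from dscmicro.synthgen import DynamicStudy


def signal_to_delta_r2(
    signal: np.ndarray | SignalTimeSeries,
    te: float,
    baseline_frames: int,
    times: np.ndarray | None = None,
    *,
    echo: str = "GRE",
    clamp: bool = False,
) -> ConcentrationCurve:
    """Convert MR signal to a relaxation-rate change curve.

    dR2(t) = -ln(S(t)/S0) / TE with S0 the mean over the pre-bolus baseline
    frames.  Non-positive samples are a data-integrity error unless
    ``clamp`` is set, in which case they are replaced by the smallest
    positive observed value (silent clamping hides corrupt data, so it is
    opt-in).
    """
    if te <= 0:
        raise ValueError("te must be positive")
    if isinstance(signal, SignalTimeSeries):
        values = signal.values
        times = signal.protocol.times
    else:
        values = np.asarray(signal, dtype=float)
        if times is None:
            raise ValueError("times required when passing a bare array")
    if baseline_frames < 1 or baseline_frames > values.size:
        raise ValueError("invalid baseline_frames")
    s0 = float(values[:baseline_frames].mean())
    if s0 <= 0:
        raise ValueError("baseline signal S0 must be positive")
    s = values
    if np.any(s <= 0):
        if not clamp:
            raise ValueError(
                "non-positive signal samples; rerun with clamp=True to "
                "replace them with the smallest positive observed value"
            )
        smallest = s[s > 0].min()
        s = np.where(s > 0, s, smallest)
    return ConcentrationCurve(-np.log(s / s0) / te, np.asarray(times), echo=echo)


# ---------------------------------------------------------------------------
# gamma-variate fitting
# ---------------------------------------------------------------------------

@dataclass
class GammaVariateFit:
    """Result of a nonlinear gamma-variate bolus fit."""

    amplitude: float
    t0: float
    r: float
    b: float
    rmse: float
    converged: bool

    def __call__(self, t: np.ndarray) -> np.ndarray:
        if not self.converged:
            raise RuntimeError("fit did not converge")
        return gamma_variate(t, self.amplitude, self.t0, self.r, self.b)

    @property
    def peak_time(self) -> float:
        return self.t0 + self.r * self.b


def _gv_model(t, log_a, t0, log_r, log_b):
    r, b = np.exp(log_r), np.exp(log_b)
    dt = t - t0
    out = np.zeros_like(t)
    pos = dt > 0
    out[pos] = np.exp(log_a + r * np.log(dt[pos]) - dt[pos] / b)
    return out


def fit_gamma_variate(curve: ConcentrationCurve) -> GammaVariateFit:
    """Least-squares fit of A*(t-t0)^r*exp(-(t-t0)/b) to a bolus curve.

    Positivity of r and b is enforced by optimizing their logarithms.
    Flat, all-negative or pathological curves return converged=False
    rather than raising, so map-scale fitting never aborts.
    """
    t, y = curve.times, curve.values
    peak = y.max()
    failed = GammaVariateFit(0.0, 0.0, 1.0, 1.0, float("inf"), False)
    if peak <= 0:
        return failed
    ipk = int(np.argmax(y))
    # arrival guess: last sample below 5% of peak before the peak
    below = np.nonzero(y[: ipk + 1] < 0.05 * peak)[0]
    t0_init = t[below[-1]] if below.size else t[0]
    best = None
    for r_init in (2.0, 4.0):
        b_init = max((t[ipk] - t0_init) / r_init, curve.dt / 4)
        a_init = peak / max(
            gamma_variate(np.array([t0_init + r_init * b_init]), 1.0,
                          t0_init, r_init, b_init)[0], 1e-300,
        )
        p0 = [np.log(a_init), t0_init, np.log(r_init), np.log(b_init)]
        try:
            popt, _ = optimize.curve_fit(
                _gv_model, t, y, p0=p0, maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except (RuntimeError, ValueError):
            continue
        resid = _gv_model(t, *popt) - y
        rmse = float(np.sqrt(np.mean(resid**2)))
        if best is None or rmse < best[1]:
            best = (popt, rmse)
    if best is None:
        return failed
    (log_a, t0, log_r, log_b), rmse = best
    return GammaVariateFit(
        amplitude=float(np.exp(log_a)), t0=float(t0), r=float(np.exp(log_r)),
        b=float(np.exp(log_b)), rmse=rmse, converged=True,
    )


# ---------------------------------------------------------------------------
# arterial input function selection
# ---------------------------------------------------------------------------

@dataclass
class ArterialInputFunction:
    """Automatically selected AIF: mean curve of the top-scoring voxels."""

    curve: ConcentrationCurve
    source_voxels: list[tuple[int, int, int]]
    quality: float


def select_aif(
    study: DynamicStudy,
    *,
    top_k: int = 5,
    quality_floor: float = 3.0,
    score_band: float = 0.5,
    clamp: bool = True,
) -> ArterialInputFunction:
    """Score every voxel for arterial character and average the best curves.

    Voxels with a baseline signal below 10% of the study median are
    treated as background and skipped.  Candidates must show a clear
    bolus (peak above ``quality_floor`` times the baseline noise SD, with
    a minimum absolute floor for noiseless data).  The score favors a
    tall, narrow (high peak-to-area ratio) and early first pass:
    ``peak^2 / (positive_area * (ttp + tr))``.  The returned AIF averages
    at most ``top_k`` candidates whose scores lie within ``score_band``
    of the best, so a single dominant artery is not diluted by tissue
    curves.  Ties are broken by the lowest linear voxel index; selection
    is deterministic and, up to index reporting, invariant to voxel
    relabeling.
    """
    protocol = study.protocol
    bf = protocol.baseline_frames
    nx, ny, nz = study.shape
    s0_all = study.signal_gre[..., :bf].mean(axis=-1)
    s0_floor = 0.1 * float(np.median(s0_all))
    scores: list[tuple[float, int, tuple[int, int, int], np.ndarray]] = []
    for lin, idx in enumerate(np.ndindex(nx, ny, nz)):
        sig = study.signal_gre[idx]
        s0 = sig[:bf].mean()
        if s0 <= 0 or s0 < s0_floor:
            continue
        try:
            conc = signal_to_delta_r2(sig, protocol.te_gre, bf,
                                      protocol.times, clamp=clamp)
        except ValueError:
            continue
        base_sd = float(conc.values[:bf].std())
        peak = conc.peak
        if peak <= max(quality_floor * base_sd, 1e-6):
            continue
        ttp = conc.peak_time
        pos_area = float(np.clip(conc.values, 0.0, None).sum()) * protocol.tr
        # tall, narrow (high peak-to-area ratio) and early first pass
        score = peak**2 / (pos_area * (ttp + protocol.tr))
        scores.append((score, lin, idx, conc.values))
    if not scores:
        raise ValueError(
            "no voxel passed the AIF quality floor; supply a manual AIF"
        )
    scores.sort(key=lambda s: (-s[0], s[1]))
    best = scores[0][0]
    chosen = [s for s in scores[:top_k] if s[0] >= score_band * best]
    mean_curve = np.mean([c[3] for c in chosen], axis=0)
    return ArterialInputFunction(
        curve=ConcentrationCurve(mean_curve, protocol.times, echo="GRE"),
        source_voxels=[c[2] for c in chosen],
        quality=float(chosen[0][0]),
    )


# ---------------------------------------------------------------------------
# SVD deconvolution
# ---------------------------------------------------------------------------

@dataclass
class ResidueEstimate:
    """Nonparametric deconvolution result for one voxel.

    CBF and CBV are in the model units of the forward convolution
    (mL/100g/min and mL/100g up to a global calibration constant); maps
    are interpreted as relative quantities.
    """

    cbf: float
    cbv: float
    mtt: float
    residue: np.ndarray


def deconvolve_svd(
    tissue: ConcentrationCurve,
    aif: ArterialInputFunction | ConcentrationCurve,
    threshold: float = 0.1,
    *,
    circulant: bool = False,
) -> ResidueEstimate:
    """Truncated-SVD deconvolution of a tissue curve by the AIF.

    Builds the discrete convolution matrix A[i, j] = dt * Ca[i - j]
    (block-circulant with 2n padding when ``circulant`` is set, which makes
    the estimate insensitive to bolus delay), zeroes singular values below
    ``threshold`` times the largest, and solves for the flow-scaled residue
    cbf/60 * R(t).  CBV is the deconvolution-free area ratio
    area(tissue)/area(AIF), so it does not depend on the threshold;
    MTT = CBV / CBF * 60.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    ca = aif.curve.values if isinstance(aif, ArterialInputFunction) else aif.values
    ct = tissue.values
    aif_times = (aif.curve.times if isinstance(aif, ArterialInputFunction)
                 else aif.times)
    if ct.shape != ca.shape or not np.allclose(tissue.times, aif_times):
        raise ValueError("tissue and AIF must share a timebase")
    if not np.any(ca > 0):
        raise ValueError("AIF is identically zero")
    dt = tissue.dt
    n = ct.size
    if circulant:
        m = 2 * n
        ca_pad = np.concatenate([ca, np.zeros(n)])
        col = np.arange(m)
        a_mat = dt * ca_pad[(col[:, None] - col[None, :]) % m]
        y = np.concatenate([ct, np.zeros(n)])
    else:
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        a_mat = np.where(i >= j, dt * np.take(ca, np.clip(i - j, 0, n - 1)), 0.0)
        y = ct
    u, s, vt = _svd(a_mat, full_matrices=False)
    s_inv = np.where(s >= threshold * s[0], 1.0 / np.where(s > 0, s, 1.0), 0.0)
    x = vt.T @ (s_inv * (u.T @ y))
    x = x[:n]

    cbv = float(np.sum(ct) / np.sum(ca))
    peak = float(np.max(x))
    if not np.any(ct != 0):
        return ResidueEstimate(cbf=0.0, cbv=0.0, mtt=float("nan"),
                               residue=np.zeros(n))
    cbf = 60.0 * peak
    mtt = cbv / cbf * 60.0 if cbf > 0 else float("nan")
    residue = x / peak if peak > 0 else x
    return ResidueEstimate(cbf=cbf, cbv=cbv, mtt=mtt, residue=residue)
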