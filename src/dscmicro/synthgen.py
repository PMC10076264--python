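"""Synthetic dual-echo DSC-MRI phantoms and longitudinal cohorts.

Every downstream stage of the pipeline is testable against known ground
truth generated here: a gamma-variate arterial bolus, tissue curves from
gamma-distributed capillary transit times, contrast extravasation in
lesion voxels, gradient-echo/spin-echo temporal decoupling (which makes
the paired-echo parametric plot trace a vortex loop), Gaussian or Rician
signal noise, and a longitudinal treatment cohort with configurable
dose-response structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.integrate import cumulative_trapezoid

from dscmicro.protocol import AcquisitionProtocol
from dscmicro.curves import ConcentrationCurve, gamma_variate

# integer codes for tissue classes in the phantom label map
TISSUE_CLASSES = {"background": 0, "NAWM": 1, "lesion": 2, "perilesional": 3, "artery": 4}
CLASS_NAMES = {v: k for k, v in TISSUE_CLASSES.items()}


# ---------------------------------------------------------------------------
# elementary forward models
# ---------------------------------------------------------------------------

def make_aif(
    amplitude: float,
    t0: float,
    r: float,
    b: float,
    protocol: AcquisitionProtocol,
) -> ConcentrationCurve:
    """Arterial input function as a gamma-variate bolus on the protocol grid.

    ``amplitude`` scales the curve (1/s units after the power term), ``t0``
    is the bolus arrival time in seconds, ``r`` and ``b`` the gamma-variate
    shape and scale.  The curve peaks at ``t0 + r*b``.
    """
    if r <= 0 or b <= 0:
        raise ValueError("gamma-variate parameters r and b must be positive")
    if not (0 <= t0 < protocol.duration):
        raise ValueError("bolus arrival t0 must lie within the acquisition window")
    t = protocol.times
    return ConcentrationCurve(gamma_variate(t, amplitude, t0, r, b), t, echo="GRE")


def gamma_residue(t: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Vascular residue function R(t) = 1 - CDF of gamma(alpha, scale=beta).

    R(t) is the fraction of tracer still inside the voxel's vasculature t
    seconds after an instantaneous arterial bolus; R(0) = 1 and R decays
    monotonically to 0.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("transit-distribution parameters must be positive")
    t = np.asarray(t, dtype=float)
    return special.gammaincc(alpha, np.clip(t, 0.0, None) / beta)


def integrated_gamma_residue(t: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Closed-form running integral G(T) = int_0^T R(tau) dtau of the gamma
    residue; G(inf) = alpha*beta = MTT."""
    t = np.clip(np.asarray(t, dtype=float), 0.0, None)
    return t * special.gammaincc(alpha, t / beta) + alpha * beta * special.gammainc(
        alpha + 1, t / beta
    )


def discrete_residue(t: np.ndarray, dt: float, alpha: float, beta: float) -> np.ndarray:
    """Cell-averaged residue samples r_i = (1/dt) * int_{t_i}^{t_i+dt} R.

    Averaging R over each frame (rather than sampling it at frame starts)
    makes the rectangle-rule convolution conserve tracer mass: the
    discrete residue area dt*sum(r) equals MTT up to window truncation,
    so area(C_t)/area(AIF) = cbv holds on coarse TR grids.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("transit-distribution parameters must be positive")
    edges = np.concatenate([t, [t[-1] + dt]])
    g = integrated_gamma_residue(edges, alpha, beta)
    # rounding in the tail can leave ~1e-16 negatives; residues are >= 0
    return np.clip(np.diff(g) / dt, 0.0, None)


def make_tissue_curve(
    aif: ConcentrationCurve,
    cbf: float,
    alpha: float,
    beta: float,
    protocol: AcquisitionProtocol,
) -> ConcentrationCurve:
    """Tissue concentration curve C_t = (cbf/60) * dt * (AIF (*) R).

    ``cbf`` is in mL/100g/min (the /60 converts to per-second flow), and
    R(t) is the survival function of a gamma(alpha, beta) transit-time
    distribution.  By tracer mass conservation area(C_t)/area(AIF) equals
    cbv = cbf * mtt / 60 up to truncation of the sampled window.
    """
    if cbf < 0:
        raise ValueError("cbf must be nonnegative")
    if alpha <= 0 or beta <= 0:
        raise ValueError("transit-distribution parameters must be positive")
    t = protocol.times
    if aif.values.shape != t.shape or not np.allclose(aif.times, t):
        raise ValueError("AIF timebase does not match the protocol grid")
    r = discrete_residue(t, protocol.tr, alpha, beta)
    conv = np.convolve(aif.values, r)[: t.size]
    return ConcentrationCurve((cbf / 60.0) * protocol.tr * conv, t, echo="GRE")


@dataclass
class DualEchoSignal:
    """Rendered voxel signal for both echoes (SE is None for single echo)."""

    gre: np.ndarray
    se: np.ndarray | None
    protocol: AcquisitionProtocol


def render_dual_echo_signal(
    conc_gre: ConcentrationCurve,
    protocol: AcquisitionProtocol,
    *,
    s0: float = 1000.0,
    kapp: float = 0.0,
    leak_reference: ConcentrationCurve | None = None,
    lag: float = 0.0,
    se_scale: float = 0.5,
    noise_sigma: float = 0.0,
    noise_model: str = "gaussian",
    rng: np.random.Generator | int | None = None,
) -> DualEchoSignal:
    """Render MR signals S_echo(t) = S0 * exp(-TE_echo * dR2_echo(t)).

    The spin-echo relaxation curve is the gradient-echo curve scaled by
    ``se_scale`` (the microvascular/macrovascular sensitivity ratio) and
    delayed by ``lag`` seconds; the temporal decoupling is what opens the
    GRE-vs-SE vortex loop.  A nonzero ``kapp`` adds the leakage term
    ``-kapp * cumulative-integral(leak_reference)`` to the GRE relaxation
    curve (signed; negate kapp for the opposite regime).  The noiseless
    render is exactly inverted by :func:`dscmicro.kinetics.signal_to_delta_r2`.
    """
    if protocol.baseline_frames < 3:
        raise ValueError("need at least 3 baseline frames")
    if lag >= protocol.duration:
        raise ValueError("gre-se lag must be shorter than the acquisition")
    t = protocol.times
    d_r2s = conc_gre.values.copy()
    if kapp != 0.0:
        if leak_reference is None:
            leak_reference = conc_gre
        cum = cumulative_trapezoid(leak_reference.values, t, initial=0.0)
        d_r2s = d_r2s - kapp * cum
    gre = s0 * np.exp(-protocol.te_gre * d_r2s)

    se = None
    if protocol.dual_echo:
        shifted = np.interp(t - lag, t, conc_gre.values, left=0.0)
        se = s0 * np.exp(-protocol.te_se * se_scale * shifted)

    if noise_sigma > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        if noise_model == "gaussian":
            gre = gre + gen.normal(0.0, noise_sigma, gre.shape)
            if se is not None:
                se = se + gen.normal(0.0, noise_sigma, se.shape)
        elif noise_model == "rician":
            gre = np.hypot(gre + gen.normal(0.0, noise_sigma, gre.shape),
                           gen.normal(0.0, noise_sigma, gre.shape))
            if se is not None:
                se = np.hypot(se + gen.normal(0.0, noise_sigma, se.shape),
                              gen.normal(0.0, noise_sigma, se.shape))
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
    return DualEchoSignal(gre=gre, se=se, protocol=protocol)


# ---------------------------------------------------------------------------
# whole-phantom generation
# ---------------------------------------------------------------------------

@dataclass
class ClassParams:
    """Per-tissue-class hemodynamic parameter ranges (uniform sampling).

    Parameterized by transit shape alpha and mean transit time (the scale
    is beta = mtt/alpha), so MTT and RTH = 1/sqrt(alpha) are controlled
    independently: heterogeneity can be elevated without shifting MTT.
    """

    cbf: tuple[float, float]        # mL/100g/min
    alpha: tuple[float, float]      # transit-distribution shape
    mtt: tuple[float, float]        # mean transit time, s
    kapp: tuple[float, float] = (0.0, 0.0)   # leakage constant, 1/s


def default_class_params() -> dict[str, ClassParams]:
    """White-matter-like defaults: NAWM with low heterogeneity (alpha ~ 4,
    RTH ~ 0.5), perilesional tissue with elevated CTH (alpha ~ 1.5, RTH
    near/above 1), lesion with contrast extravasation and moderately
    elevated CTH at NAWM-like MTT."""
    return {
        "NAWM": ClassParams(cbf=(20.0, 28.0), alpha=(3.6, 4.4), mtt=(3.8, 4.2)),
        "perilesional": ClassParams(cbf=(16.0, 24.0), alpha=(1.3, 1.7),
                                    mtt=(4.5, 5.5)),
        "lesion": ClassParams(cbf=(12.0, 20.0), alpha=(1.6, 2.4),
                              mtt=(3.8, 4.2), kapp=(0.006, 0.014)),
    }


@dataclass
class PhantomSpec:
    """Geometry, physiology, and noise of a synthetic dual-echo study."""

    shape: tuple[int, int, int] = (32, 32, 3)
    protocol: AcquisitionProtocol = field(
        default_factory=lambda: AcquisitionProtocol(
            tr=1.5, te_gre=0.040, te_se=0.096, n_dynamics=80, baseline_frames=10
        )
    )
    class_params: dict[str, ClassParams] = field(default_factory=default_class_params)
    # power-injected pediatric bolus: compact first pass (FWHM ~ 4 s)
    aif_amplitude: float = 3.5
    aif_t0: float = 15.0
    aif_r: float = 3.0
    aif_b: float = 0.8
    s0: float = 1000.0
    artery_scale: float = 5.0        # blood-pool amplitude vs tissue units
    se_scale: float = 0.5
    gre_se_lag: float = 1.5          # seconds; one frame at TR = 1.5 s
    snr: float = 100.0               # baseline signal-to-noise S0/sigma
    noise_model: str = "gaussian"
    lesion_radius: float = 4.0       # voxels; perilesional shell is +2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isinf(self.snr) or self.snr > 0):
            raise ValueError("SNR must be positive (or inf for noiseless)")
        if int(np.prod(self.shape)) < 2:
            raise ValueError("phantom grid must contain at least 2 voxels")


@dataclass
class GroundTruth:
    """Voxel-aligned truth maps for a phantom study.

    Satisfies the central volume theorem exactly: cbv = cbf * mtt / 60
    wherever cbf > 0.  kapp is zero outside the lesion class.
    """

    cbf: np.ndarray            # mL/100g/min
    cbv: np.ndarray            # mL/100g
    mtt: np.ndarray            # s
    cth: np.ndarray            # s
    kapp: np.ndarray           # 1/s
    gre_se_lag: np.ndarray     # s
    tissue_class: np.ndarray   # int codes, see TISSUE_CLASSES

    def mask(self, name: str) -> np.ndarray:
        return self.tissue_class == TISSUE_CLASSES[name]

    @property
    def rth(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.mtt > 0, self.cth / self.mtt, np.nan)


@dataclass
class DynamicStudy:
    """4D dual-echo signal volumes plus protocol and optional ground truth.

    ``aif_true`` and ``leak_reference`` hold the exact curves the generator
    injected (bolus and leakage reference shape), enabling exact
    forward-inverse verification without re-deriving them.
    """

    signal_gre: np.ndarray               # (x, y, z, t)
    signal_se: np.ndarray | None
    protocol: AcquisitionProtocol
    truth: GroundTruth | None = None
    aif_true: ConcentrationCurve | None = None
    leak_reference: ConcentrationCurve | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal_gre.shape[:3]

    def voxel_signal(self, idx: tuple[int, int, int], echo: str = "GRE") -> np.ndarray:
        vol = self.signal_gre if echo == "GRE" else self.signal_se
        if vol is None:
            raise ValueError("study has no spin-echo series")
        return vol[idx]


def _phantom_labels(shape: tuple[int, int, int], lesion_radius: float) -> np.ndarray:
    """Concentric layout: central lesion sphere, perilesional shell,
    NAWM elsewhere, a single artery voxel and a background rim corner."""
    nx, ny, nz = shape
    labels = np.full(shape, TISSUE_CLASSES["NAWM"], dtype=np.int8)
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    xx, yy, zz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    # in-plane distance only, so thin slabs still get a full shell
    dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    labels[dist <= lesion_radius] = TISSUE_CLASSES["lesion"]
    shell = (dist > lesion_radius) & (dist <= lesion_radius + 2.0)
    labels[shell] = TISSUE_CLASSES["perilesional"]
    labels[0, :2, :] = TISSUE_CLASSES["background"]
    labels[0, 0, 0] = TISSUE_CLASSES["artery"]
    return labels


def make_phantom(spec: PhantomSpec) -> DynamicStudy:
    """Build a dual-echo phantom study with voxel-aligned ground truth.

    The artery voxel carries the (earliest, tallest) bolus itself; tissue
    voxels carry gamma-residue convolutions with class-specific physiology;
    lesion voxels leak contrast at kapp_true against the noiseless NAWM
    population-mean curve; background voxels are flat at 2% of S0.
    """
    protocol = spec.protocol
    labels = _phantom_labels(spec.shape, spec.lesion_radius)
    rng = np.random.default_rng(spec.seed)
    t = protocol.times
    n = protocol.n_dynamics

    aif = make_aif(spec.aif_amplitude, spec.aif_t0, spec.aif_r, spec.aif_b, protocol)

    shape = spec.shape
    cbf = np.zeros(shape)
    mtt = np.zeros(shape)
    cth = np.zeros(shape)
    kapp = np.zeros(shape)
    alpha_map = np.zeros(shape)
    beta_map = np.zeros(shape)

    for name, params in spec.class_params.items():
        m = labels == TISSUE_CLASSES[name]
        k = int(m.sum())
        if k == 0:
            continue
        a = rng.uniform(*params.alpha, size=k)
        m_tt = rng.uniform(*params.mtt, size=k)
        b = m_tt / a
        cbf[m] = rng.uniform(*params.cbf, size=k)
        alpha_map[m] = a
        beta_map[m] = b
        mtt[m] = m_tt
        cth[m] = np.sqrt(a) * b
        kapp[m] = rng.uniform(*params.kapp, size=k)

    # NAWM population-mean concentration curve = leakage reference shape
    nawm_idx = np.argwhere(labels == TISSUE_CLASSES["NAWM"])
    nawm_curves = np.stack(
        [
            make_tissue_curve(aif, cbf[tuple(i)], alpha_map[tuple(i)],
                              beta_map[tuple(i)], protocol).values
            for i in nawm_idx[:: max(1, len(nawm_idx) // 64)]
        ]
    )
    leak_ref = ConcentrationCurve(nawm_curves.mean(axis=0), t, echo="GRE")

    noise_sigma = 0.0 if np.isinf(spec.snr) else spec.s0 / spec.snr
    sig_gre = np.empty(shape + (n,))
    sig_se = np.empty(shape + (n,)) if protocol.dual_echo else None
    lag_map = np.zeros(shape)

    for idx in np.ndindex(*shape):
        cls = CLASS_NAMES[int(labels[idx])]
        if cls == "background":
            base = np.full(n, 0.02 * spec.s0)
            sig_gre[idx] = base + (
                rng.normal(0.0, noise_sigma, n) if noise_sigma else 0.0
            )
            if sig_se is not None:
                sig_se[idx] = base + (
                    rng.normal(0.0, noise_sigma, n) if noise_sigma else 0.0
                )
            continue
        if cls == "artery":
            # pure blood-pool voxel: the bolus itself, at arterial amplitude
            conc = ConcentrationCurve(spec.artery_scale * aif.values, t,
                                      echo="GRE")
            lag = 0.0
        else:
            conc = make_tissue_curve(
                aif, cbf[idx], alpha_map[idx], beta_map[idx], protocol
            )
            lag = spec.gre_se_lag
        lag_map[idx] = lag
        rendered = render_dual_echo_signal(
            conc,
            protocol,
            s0=spec.s0,
            kapp=kapp[idx],
            leak_reference=leak_ref,
            lag=lag,
            se_scale=spec.se_scale,
            noise_sigma=noise_sigma,
            noise_model=spec.noise_model,
            rng=rng,
        )
        sig_gre[idx] = rendered.gre
        if sig_se is not None:
            sig_se[idx] = rendered.se

    cbv = cbf * mtt / 60.0
    truth = GroundTruth(
        cbf=cbf, cbv=cbv, mtt=mtt, cth=cth, kapp=kapp,
        gre_se_lag=lag_map, tissue_class=labels,
    )
    return DynamicStudy(
        signal_gre=sig_gre, signal_se=sig_se, protocol=protocol, truth=truth,
        aif_true=aif, leak_reference=leak_ref,
    )


# ---------------------------------------------------------------------------
# longitudinal cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Study design for a synthetic longitudinal treatment cohort.

    Groups mirror a gene-therapy trial layout: GT (lentiviral gene therapy),
    allo-HSCT (allogeneic transplant), HEM (untreated hemizygotes without
    cerebral disease, flat over time by construction) and CON (non-carrier
    controls, single visit).  Effect sizes are expressed in units of the
    between-subject SD; ``vcn_growth_slope`` is the drop in monthly lesion
    growth rate (%/month) per unit vector copy number.
    """

    n_gt: int = 13
    n_hsct: int = 6
    n_hem: int = 11
    n_con: int = 7
    visit_days: tuple[float, ...] = (0.0, 45.0, 365.0, 730.0)
    # treatment effects, in between-subject SD units (post vs pre)
    effect_rth: float = 1.0
    effect_va: float = 1.0
    effect_kapp: float = 1.5
    effect_growth: float = 1.5
    vcn_growth_slope: float = 4.0    # %/month lesion-growth reduction per VCN
    vcn_fa_slope: float = 0.02       # FA retained per VCN per year
    # population means and between-subject SDs
    rth_mean: float = 1.10
    rth_sd: float = 0.08
    va_mean: float = 1.00
    va_sd: float = 0.15
    kapp_mean: float = 0.010
    kapp_sd: float = 0.003
    growth_mean: float = 8.0         # %/month pre-treatment lesion growth
    growth_sd: float = 2.5
    residual_sd_frac: float = 0.35   # within-subject noise as fraction of SD
    age_range: tuple[float, float] = (4.0, 14.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("n_gt", "n_hsct", "n_hem", "n_con"):
            if getattr(self, nm) < 0:
                raise ValueError(f"group size {nm} must be nonnegative")
        days = np.asarray(self.visit_days)
        if days.size >= 2 and not np.all(np.diff(days) > 0):
            raise ValueError("visit days must be strictly increasing")
        for nm in ("rth_sd", "va_sd", "kapp_sd", "growth_sd"):
            if getattr(self, nm) < 0:
                raise ValueError("between-subject SDs must be nonnegative")


COHORT_COLUMNS = [
    "subject", "group", "age", "visit_day", "lesion_volume", "lesion_fa",
    "adc", "vcn_product", "vcn_blood", "rth", "va", "kapp",
    "cth_perilesional",
]


def make_cohort(design: CohortDesign) -> pd.DataFrame:
    """Simulate one subject-visit-per-row longitudinal cohort table.

    Treated subjects (GT, allo-HSCT) move from a diseased baseline toward
    normalized RTH/VA/K_app after treatment, with the configured effect
    sizes; in the GT arm the vector copy number linearly reduces lesion
    growth and FA decline.  HEM subjects have no secular trend: their
    expected values are constant across visits.  CON subjects contribute a
    single normative visit.
    """
    rng = np.random.default_rng(design.seed)
    days = np.asarray(design.visit_days, dtype=float)
    rows: list[dict] = []
    sid = 0
    res = design.residual_sd_frac

    def subject_base(group: str) -> dict:
        return {
            "age": rng.uniform(*design.age_range),
            "rth0": rng.normal(design.rth_mean, design.rth_sd),
            "va0": rng.normal(design.va_mean, design.va_sd),
            "kapp0": rng.normal(design.kapp_mean, design.kapp_sd),
            "growth0": rng.normal(design.growth_mean, design.growth_sd),
            "fa0": rng.uniform(0.35, 0.50),
            "adc0": rng.normal(8.5e-4, 0.5e-4),
            "vol0": rng.lognormal(np.log(12.0), 0.5),
        }

    def emit(group: str, base: dict, day: float, frac_treated: float,
             vcn_product: float, vcn_blood: float) -> None:
        """frac_treated in [0, 1]: how much of the treatment effect has
        accrued by this visit (0 pre-treatment, 1 fully established)."""
        nonlocal rows
        rth = base["rth0"] - frac_treated * design.effect_rth * design.rth_sd
        va = base["va0"] + frac_treated * design.effect_va * design.va_sd
        kapp = base["kapp0"] - frac_treated * design.effect_kapp * design.kapp_sd
        growth = base["growth0"] - frac_treated * (
            design.effect_growth * design.growth_sd
            + design.vcn_growth_slope * vcn_product
        )
        months = day / 30.44
        # lesion volume integrates the (piecewise-constant) growth rate
        vol = base["vol0"] * (1.0 + growth / 100.0) ** months
        fa = base["fa0"] - 0.01 * months * max(growth, 0.0) / design.growth_mean
        fa += design.vcn_fa_slope * vcn_product * (day / 365.0) * frac_treated
        rows.append({
            "subject": f"S{sid:03d}",
            "group": group,
            "age": base["age"] + day / 365.25,
            "visit_day": day,
            "lesion_volume": max(vol + rng.normal(0, 0.02 * base["vol0"]), 0.0),
            "lesion_fa": float(np.clip(fa + rng.normal(0, 0.01), 0.0, 1.0)),
            "adc": base["adc0"] + rng.normal(0, 1e-5),
            "vcn_product": vcn_product,
            "vcn_blood": vcn_blood,
            "rth": max(rth + rng.normal(0, res * design.rth_sd), 1e-6),
            "va": max(va + rng.normal(0, res * design.va_sd), 0.0),
            "kapp": kapp + rng.normal(0, res * design.kapp_sd),
            "cth_perilesional": max(
                rth * 4.0 + rng.normal(0, res * design.rth_sd * 4.0), 1e-6
            ),
        })

    for _ in range(design.n_gt):
        base = subject_base("GT")
        vcn_p = rng.uniform(0.4, 2.5)
        vcn_b = max(vcn_p * rng.uniform(0.4, 0.9), 0.01)
        for day in days:
            frac = 0.0 if day <= 0 else min(day / 365.0, 1.0)
            emit("GT", base, day, frac, vcn_p, vcn_b)
        sid += 1
    for _ in range(design.n_hsct):
        base = subject_base("allo-HSCT")
        for day in days:
            frac = 0.0 if day <= 0 else min(day / 365.0, 1.0)
            emit("allo-HSCT", base, day, frac, np.nan, np.nan)
        sid += 1
    for _ in range(design.n_hem):
        base = subject_base("HEM")
        base["growth0"] = 0.0
        base["vol0"] = 0.0
        for day in days:
            emit("HEM", base, day, 0.0, np.nan, np.nan)  # flat: no trend
        sid += 1
    for _ in range(design.n_con):
        base = subject_base("CON")
        base["growth0"] = 0.0
        base["vol0"] = 0.0
        base["rth0"] = rng.normal(design.rth_mean - 2.0 * design.rth_sd,
                                  design.rth_sd)
        base["va0"] = rng.normal(design.va_mean + 2.0 * design.va_sd,
                                 design.va_sd)
        base["kapp0"] = rng.normal(0.0, design.kapp_sd)
        emit("CON", base, 0.0, 0.0, np.nan, np.nan)
        sid += 1

    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
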