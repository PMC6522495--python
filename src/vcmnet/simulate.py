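"""Seeded generators for every input the pipeline consumes, with ground truth.

The expression generator emulates a 4-stage maturation study (hESC,
hESC-VCM, fetal-VCM, adult-VCM; 3 replicate arrays per stage) with planted
co-expression modules: a large maturation-rising module, a
respiration/mitochondria-like module rising with differentiation, and a
pluripotency module falling with maturation.  Module genes load on their
module's stage profile with uniform(0.5, 1) loadings; everything else is
noise, part of which carries planted differential-expression shifts,
"immature-stage intermediate" expression windows, or adult-high profiles, so
that every downstream operation (module detection, DE testing, the window
filter, the candidate cascade) has an attached truth to be scored against.

Trace generators produce Ca2+ transients (double-exponential kinetics),
action potentials (half-cosine upstroke, linear plateau and repolarization,
so every duration crossing has a closed form), activation-time maps (planar
or radial wavefront plus Gaussian timing jitter) and cantilever deflection
twitch trains (the inverse of the deflection-to-force transform applied to a
planted force).  Each returns its exact truth alongside the trace.

Reproducibility: every generator is a pure function of (config, seed held in
the config).  The expression generator fans a root ``SeedSequence`` out into
per-component substreams (loadings, noise, gene shuffling), so outputs are
bit-identical for identical configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .assays import ActivationMap, Trace
from .expression_io import DEFAULT_STAGES, ExpressionMatrix, GeneSetCollection
from .modules import GREY, PALETTE, ModuleAssignment

#: The two maturation contrasts: immature-stage cells vs each mature stage.
DEFAULT_CONTRASTS = (("hESC-VCM", "fetal-VCM"), ("hESC-VCM", "adult-VCM"))


# -- expression ------------------------------------------------------------


@dataclass(frozen=True)
class PlantedModule:
    """A planted co-expression module: size, per-stage profile, signal scale."""

    size: int
    profile: tuple[float, ...]
    signal_sd: float = 1.0


#: Stage profiles (z-scale, normalized internally).  In an unsigned network
#: anti-correlated profiles merge into one module, so the three planted
#: profiles are mutually orthogonal stage contrasts: maturation-rising
#: (linear), transiently-repressed (quadratic; e.g. cell-cycle/biosynthesis
#: dipping in the cardiomyocyte stages) and immature-peaking (cubic).
DEFAULT_MODULES = (
    PlantedModule(120, (-3.0, -1.0, 1.0, 3.0)),
    PlantedModule(80, (1.0, -1.0, -1.0, 1.0)),
    PlantedModule(50, (-1.0, 3.0, -3.0, 1.0)),
)

#: Stage-mean offsets (log2 units) for the planted in-window genes: low-ish
#: everywhere, immature stage sitting ~0.5 sd above the gene mean, and a deep
#: fetal drop that makes the gene clearly DE.  The true candidates get a
#: silent-vs-expressed scale drop (~10 log2 units) so their differential
#: expression survives BH correction with n = 3 replicates per stage.
INTERMEDIATE_PROFILE = (0.25, 0.0, -4.0, 0.25)
CANDIDATE_PROFILE = (0.25, 0.0, -10.0, 0.25)

#: Immature-stage dip (log2 units) given to the designated "adult-high"
#: module-1 genes so their immature-stage z robustly fails the (0, 1) window.
ADULT_HIGH_DIP = -0.8
ADULT_HIGH_LOADING = 1.2


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Study-design parameters of the synthetic expression experiment."""

    n_genes: int = 500
    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates: int = 3
    modules: tuple[PlantedModule, ...] = DEFAULT_MODULES
    noise_sd: float = 0.5
    n_de: int = 40  # planted DE genes in the noise pool
    de_delta: float = 2.0  # log2-unit shift at the immature stage
    n_candidates: int = 2  # true chromatin-remodeler candidates
    n_intermediate: int = 10  # in-window genes (pass the (0, 1) filter)
    n_adult_high: int = 10  # out-of-window genes (fail the filter)
    n_regulators: int = 50
    n_remodelers: int = 12
    n_cardiac: int = 11
    baseline: float = 8.0
    seed: int = 0


@dataclass
class SimulatedStudy:
    """Synthetic expression matrix bundled with all ground-truth objects."""

    matrix: ExpressionMatrix
    modules: ModuleAssignment  # truth labels (candidates belong to turquoise)
    gene_sets: GeneSetCollection
    de_truth: pd.DataFrame  # true per-contrast lfc + is_de flag per gene
    candidates: list[str]
    window_pass: list[str]
    window_fail: list[str]
    module_profiles: dict[str, np.ndarray]  # color -> per-stage z profile
    config: ExpressionSimConfig


def _normalize_profile(profile: tuple[float, ...]) -> np.ndarray:
    p = np.asarray(profile, dtype=float)
    p = p - p.mean()
    sd = p.std(ddof=0)
    if sd == 0:
        raise ValueError("constant module profile")
    return p / sd


def simulate_expression(cfg: ExpressionSimConfig) -> SimulatedStudy:
    """Generate the 4-stage expression study with attached ground truth."""
    n_stage = len(cfg.stages)
    if any(len(mod.profile) != n_stage for mod in cfg.modules):
        raise ValueError("module profiles must have one value per stage")
    if any(mod.signal_sd < 0 for mod in cfg.modules) or cfg.noise_sd <= 0:
        raise ValueError("signal sds must be >= 0 and noise sd > 0")
    n_module_genes = sum(mod.size for mod in cfg.modules)
    n_special = cfg.n_de + cfg.n_intermediate
    if n_module_genes + n_special > cfg.n_genes:
        raise ValueError("planted gene groups exceed n_genes")
    if cfg.modules and cfg.n_candidates + cfg.n_adult_high > cfg.modules[0].size:
        raise ValueError("candidates + adult-high genes exceed the largest module")
    if cfg.n_adult_high and not cfg.modules:
        raise ValueError("adult-high genes require a planted module")

    root = np.random.SeedSequence(cfg.seed)
    rng_load, rng_noise, rng_shuffle = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    n_samples = n_stage * cfg.replicates
    stage_idx = np.repeat(np.arange(n_stage), cfg.replicates)
    stage_labels = [cfg.stages[i] for i in stage_idx]
    sample_ids = [
        f"{cfg.stages[i]}_r{r + 1}"
        for i in range(n_stage)
        for r in range(cfg.replicates)
    ]

    signal = np.zeros((cfg.n_genes, n_samples))
    labels = [GREY] * cfg.n_genes
    true_lfc = {c: np.zeros(cfg.n_genes) for c in DEFAULT_CONTRASTS}

    # module order by size determines the truth color (largest = turquoise)
    order = sorted(range(len(cfg.modules)), key=lambda i: (-cfg.modules[i].size, i))
    colors = {
        mi: (PALETTE[rank] if rank < len(PALETTE) else f"module{rank + 1}")
        for rank, mi in enumerate(order)
    }
    module_profiles: dict[str, np.ndarray] = {}

    def _stage_values(per_stage: np.ndarray) -> np.ndarray:
        return per_stage[stage_idx]

    def _record_lfc(rows: np.ndarray, per_stage: np.ndarray) -> None:
        for contrast in DEFAULT_CONTRASTS:
            ia, ib = cfg.stages.index(contrast[0]), cfg.stages.index(contrast[1])
            true_lfc[contrast][rows] += per_stage[ia] - per_stage[ib]

    imm = cfg.stages.index("hESC-VCM") if "hESC-VCM" in cfg.stages else 1
    cursor = 0
    candidate_rows: list[int] = []
    adult_rows: list[int] = []
    module_rows: dict[int, list[int]] = {}
    for mi, mod in enumerate(cfg.modules):
        profile = _normalize_profile(mod.profile) * mod.signal_sd
        module_profiles[colors[mi]] = _normalize_profile(mod.profile)
        rows = list(range(cursor, cursor + mod.size))
        module_rows[mi] = rows
        loadings = rng_load.uniform(0.5, 1.0, size=mod.size)
        if mi == order[0]:
            # the largest module hosts the true candidates (bespoke profile,
            # no module signal) and the adult-high window-fail genes (strong
            # module loading plus an immature-stage dip)
            candidate_rows = rows[: cfg.n_candidates]
            loadings[: cfg.n_candidates] = 0.0
            adult_rows = rows[cfg.n_candidates : cfg.n_candidates + cfg.n_adult_high]
            loadings[cfg.n_candidates : cfg.n_candidates + cfg.n_adult_high] = (
                ADULT_HIGH_LOADING
            )
        block = np.outer(loadings, _stage_values(profile))
        signal[rows] += block
        for r, load in zip(rows, loadings):
            labels[r] = colors[mi]
            _record_lfc(np.array([r]), profile * load)
        cursor += mod.size

    cand_profile = np.asarray(CANDIDATE_PROFILE, dtype=float)
    inter_profile = np.asarray(INTERMEDIATE_PROFILE, dtype=float)
    for r in candidate_rows:
        signal[r] += _stage_values(cand_profile)
        _record_lfc(np.array([r]), cand_profile)
    dip = np.zeros(n_stage)
    dip[imm] = ADULT_HIGH_DIP
    for r in adult_rows:
        signal[r] += _stage_values(dip)
        _record_lfc(np.array([r]), dip)

    de_rows = np.arange(cursor, cursor + cfg.n_de)
    cursor += cfg.n_de
    for j, r in enumerate(de_rows):
        sign = 1.0 if j % 2 == 0 else -1.0
        shift = np.zeros(n_stage)
        shift[imm] = sign * cfg.de_delta
        signal[r] += _stage_values(shift)
        _record_lfc(np.array([r]), shift)

    inter_rows = np.arange(cursor, cursor + cfg.n_intermediate)
    cursor += cfg.n_intermediate
    for r in inter_rows:
        signal[r] += _stage_values(inter_profile)
        _record_lfc(np.array([r]), inter_profile)

    values = cfg.baseline + signal + rng_noise.normal(0.0, cfg.noise_sd, signal.shape)

    perm = rng_shuffle.permutation(cfg.n_genes)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(cfg.n_genes)
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]

    def _ids(rows) -> list[str]:
        return [gene_ids[inv[r]] for r in rows]

    matrix = ExpressionMatrix(gene_ids, sample_ids, stage_labels, values[perm])
    assignment = ModuleAssignment(gene_ids, [labels[r] for r in perm])

    de_frame = pd.DataFrame(
        {
            f"lfc_{a}_vs_{b}": true_lfc[(a, b)][perm]
            for a, b in DEFAULT_CONTRASTS
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    de_frame["is_de"] = (de_frame.abs() >= 1.0).any(axis=1)

    # annotation truth: regulators straddle the largest module and the noise
    # pool; remodelers are a regulator subset containing the true candidates
    top_rows = module_rows[order[0]] if cfg.modules else []
    non_cand = [r for r in top_rows if r not in candidate_rows]
    noise_pool = list(range(cursor, cfg.n_genes))
    n_mod_reg = min(max(cfg.n_regulators - 10, 0), len(non_cand))
    regulator_rows = candidate_rows + non_cand[:n_mod_reg]
    regulator_rows += noise_pool[: max(cfg.n_regulators - len(regulator_rows), 0)]
    remodeler_rows = candidate_rows + non_cand[: max(cfg.n_remodelers - len(candidate_rows), 0)]
    cardiac_rows = non_cand[: cfg.n_cardiac]
    sets = {
        "transcriptional_regulators": set(_ids(regulator_rows)),
        "chromatin_remodelers": set(_ids(remodeler_rows)),
        "cardiac_muscle_development": set(_ids(cardiac_rows)),
    }
    go_rows = (
        [(g, "GO:TRANSCRIPTION_REGULATION") for g in sorted(sets["transcriptional_regulators"])]
        + [(g, "GO:0016568") for g in sorted(sets["chromatin_remodelers"])]
        + [(g, "GO:CARDIAC_MUSCLE_DEV") for g in sorted(sets["cardiac_muscle_development"])]
    )
    gene_sets = GeneSetCollection(sets, pd.DataFrame(go_rows, columns=["gene", "term"]))

    return SimulatedStudy(
        matrix=matrix,
        modules=assignment,
        gene_sets=gene_sets,
        de_truth=de_frame,
        candidates=_ids(candidate_rows),
        window_pass=_ids(list(inter_rows) + candidate_rows),
        window_fail=_ids(adult_rows),
        module_profiles=module_profiles,
        config=cfg,
    )


def null_config(cfg: ExpressionSimConfig | None = None, seed: int = 0) -> ExpressionSimConfig:
    """The zero-signal negative control: same design, no planted structure."""
    cfg = cfg or ExpressionSimConfig()
    return replace(
        cfg,
        modules=tuple(replace(m, signal_sd=0.0) for m in cfg.modules),
        n_de=0,
        n_candidates=0,
        n_intermediate=0,
        n_adult_high=0,
        seed=seed,
    )


# -- Ca2+ transient traces -------------------------------------------------


def _transient_kernel(tau_rise: float, tau_decay: float):
    """Normalized double-exponential kernel and its analytic peak time."""
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("kinetic time constants must be positive")
    t_peak = tau_rise * np.log1p(tau_decay / tau_rise)

    def g(t):
        t = np.asarray(t, dtype=float)
        return np.where(
            t <= 0, 0.0, (1.0 - np.exp(-t / tau_rise)) * np.exp(-t / tau_decay)
        )

    peak = float(g(t_peak))
    return lambda t: g(t) / peak, t_peak


@dataclass(frozen=True)
class CalciumSimConfig:
    n_beats: int = 10
    pacing_hz: float = 1.0
    tau_rise: float = 0.03  # s
    tau_decay: float = 0.25  # s
    peak_dff: float = 0.8
    f_base: float = 150.0  # a.u.
    background: float = 50.0  # a.u.
    noise_sd: float = 4.0  # a.u. (SNR 20 against the 80 a.u. peak)
    sampling_rate: float = 500.0  # Hz
    pre_s: float = 0.5  # quiescent baseline before the first beat
    seed: int = 0


@dataclass
class CalciumTruth:
    amplitude: float  # planted peak dF/F
    upstroke_time: float  # s, 10% -> peak on the noiseless kernel
    decay50_time: float  # s, peak -> half amplitude on the noiseless kernel
    f_base: float
    background: float
    baseline_window: tuple[float, float]


def simulate_calcium_trace(cfg: CalciumSimConfig) -> tuple[Trace, CalciumTruth]:
    """Paced Ca2+ transient train with closed-form kinetic truth."""
    ghat, t_peak = _transient_kernel(cfg.tau_rise, cfg.tau_decay)
    horizon = 10 * cfg.tau_decay
    t10 = brentq(lambda t: ghat(t) - 0.1, 1e-9, t_peak)
    t50 = brentq(lambda t: ghat(t) - 0.5, t_peak, t_peak + horizon)
    truth = CalciumTruth(
        amplitude=cfg.peak_dff,
        upstroke_time=t_peak - t10,
        decay50_time=t50 - t_peak,
        f_base=cfg.f_base,
        background=cfg.background,
        baseline_window=(0.0, cfg.pre_s),
    )
    duration = cfg.pre_s + cfg.n_beats / cfg.pacing_hz
    t = np.arange(int(round(duration * cfg.sampling_rate))) / cfg.sampling_rate
    stim = cfg.pre_s + np.arange(cfg.n_beats) / cfg.pacing_hz
    amp_f = cfg.peak_dff * (cfg.f_base - cfg.background)
    f = np.full_like(t, cfg.f_base)
    for s in stim:
        f += amp_f * ghat(t - s)
    rng = np.random.default_rng(cfg.seed)
    f += rng.normal(0.0, cfg.noise_sd, f.shape)
    return Trace(f, cfg.sampling_rate, kind="fluorescence", stim_times=stim), truth


# -- action potential traces -----------------------------------------------


@dataclass(frozen=True)
class APSimConfig:
    n_beats: int = 5
    pacing_hz: float = 1.0
    mdp: float = -60.0  # mV
    peak: float = 40.0  # mV
    t_pre: float = 0.1  # s of diastole before the upstroke
    t_rise: float = 0.004  # s, half-cosine upstroke
    plateau_v: float = 20.0  # mV at the end of the plateau decline
    t_plateau: float = 0.2  # s of linear peak -> plateau_v decline
    t_fall: float = 0.1  # s of linear plateau_v -> mdp repolarization
    sampling_rate: float = 1000.0  # Hz
    noise_sd: float = 1.0  # mV
    seed: int = 0


@dataclass
class APTruth:
    amplitude: float  # mV
    mdp: float  # mV
    apd50: float  # ms, from the analytic max-dV/dt instant
    apd90: float  # ms
    upstroke_velocity: float  # mV/ms (analytic half-cosine maximum)
    decay_velocity: float  # mV/ms
    firing_rate: float  # Hz


def _ap_truth(cfg: APSimConfig) -> APTruth:
    amp = cfg.peak - cfg.mdp
    t_up = cfg.t_pre + cfg.t_rise / 2.0  # analytic max-dV/dt instant
    t_peak = cfg.t_pre + cfg.t_rise

    def crossing(level: float) -> float:
        if level >= cfg.plateau_v:  # within the plateau decline
            frac = (cfg.peak - level) / (cfg.peak - cfg.plateau_v)
            return t_peak + frac * cfg.t_plateau
        frac = (cfg.plateau_v - level) / (cfg.plateau_v - cfg.mdp)
        return t_peak + cfg.t_plateau + frac * cfg.t_fall

    apd50 = (crossing(cfg.peak - 0.5 * amp) - t_up) * 1000.0
    apd90 = (crossing(cfg.peak - 0.9 * amp) - t_up) * 1000.0
    return APTruth(
        amplitude=amp,
        mdp=cfg.mdp,
        apd50=apd50,
        apd90=apd90,
        upstroke_velocity=amp * np.pi / (2.0 * cfg.t_rise) / 1000.0,
        decay_velocity=-(cfg.plateau_v - cfg.mdp) / cfg.t_fall / 1000.0,
        firing_rate=cfg.pacing_hz,
    )


def simulate_ap_trace(cfg: APSimConfig) -> tuple[Trace, APTruth]:
    """Paced action-potential train with analytic APD crossings."""
    beat_T = 1.0 / cfg.pacing_hz
    if cfg.t_pre + cfg.t_rise + cfg.t_plateau + cfg.t_fall >= beat_T:
        raise ValueError("AP segments do not fit in one pacing cycle")
    n = int(round(cfg.n_beats * beat_T * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate
    phase = t % beat_T
    v = np.full(n, cfg.mdp)
    amp = cfg.peak - cfg.mdp
    rise = (phase >= cfg.t_pre) & (phase < cfg.t_pre + cfg.t_rise)
    v[rise] = cfg.mdp + amp / 2.0 * (
        1.0 - np.cos(np.pi * (phase[rise] - cfg.t_pre) / cfg.t_rise)
    )
    t_peak = cfg.t_pre + cfg.t_rise
    plateau = (phase >= t_peak) & (phase < t_peak + cfg.t_plateau)
    v[plateau] = cfg.peak - (cfg.peak - cfg.plateau_v) * (
        phase[plateau] - t_peak
    ) / cfg.t_plateau
    t_fall0 = t_peak + cfg.t_plateau
    fall = (phase >= t_fall0) & (phase < t_fall0 + cfg.t_fall)
    v[fall] = cfg.plateau_v - (cfg.plateau_v - cfg.mdp) * (phase[fall] - t_fall0) / cfg.t_fall
    rng = np.random.default_rng(cfg.seed)
    v = v + rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else v
    stim = cfg.t_pre + np.arange(cfg.n_beats) * beat_T
    return Trace(v, cfg.sampling_rate, kind="voltage", stim_times=stim), _ap_truth(cfg)


# -- activation maps -------------------------------------------------------


@dataclass(frozen=True)
class MapSimConfig:
    shape: tuple[int, int] = (40, 40)
    pixel_pitch: float = 0.25  # mm per pixel (10 mm field of view)
    cv_mm_s: float = 80.0
    mode: str = "radial"  # radial | planar
    origin: tuple[float, float] = (20.0, 0.0)  # (row, col) of the stimulus
    jitter_ms: float = 2.0
    seed: int = 0


def simulate_activation_map(cfg: MapSimConfig) -> tuple[ActivationMap, float]:
    """Wavefront activation-time map plus the planted conduction velocity."""
    if cfg.cv_mm_s <= 0:
        raise ValueError("conduction velocity must be positive")
    rows, cols = np.indices(cfg.shape)
    x = (cols - cfg.origin[1]) * cfg.pixel_pitch
    y = (rows - cfg.origin[0]) * cfg.pixel_pitch
    if cfg.mode == "radial":
        dist = np.hypot(x, y)
    elif cfg.mode == "planar":
        dist = x
    else:
        raise ValueError(f"unknown map mode {cfg.mode!r}")
    times = dist / cfg.cv_mm_s * 1000.0
    if cfg.jitter_ms > 0:
        rng = np.random.default_rng(cfg.seed)
        times = times + rng.normal(0.0, cfg.jitter_ms, times.shape)
    return ActivationMap(times, cfg.pixel_pitch, cfg.origin), cfg.cv_mm_s


# -- force traces ----------------------------------------------------------


@dataclass(frozen=True)
class ForceSimConfig:
    n_twitches: int = 8
    pacing_hz: float = 1.0
    twitch_force: float = 20.0  # uN
    spring_constant: float = 0.5  # uN/um
    baseline_deflection: float = 5.0  # um of passive tension
    tau_rise: float = 0.05  # s
    tau_decay: float = 0.15  # s
    noise_sd: float = 0.05  # um
    sampling_rate: float = 200.0  # Hz
    pre_s: float = 0.5
    seed: int = 0


def simulate_force_trace(cfg: ForceSimConfig) -> tuple[Trace, float]:
    """Cantilever deflection twitch train; truth is the planted twitch force.

    The deflection is the inverse of the cantilever transform applied to the
    planted force: peak deflection amplitude = twitch_force / k above the
    passive baseline.
    """
    if cfg.spring_constant <= 0 or cfg.twitch_force <= 0:
        raise ValueError("spring constant and twitch force must be positive")
    ghat, _ = _transient_kernel(cfg.tau_rise, cfg.tau_decay)
    duration = cfg.pre_s + cfg.n_twitches / cfg.pacing_hz
    t = np.arange(int(round(duration * cfg.sampling_rate))) / cfg.sampling_rate
    stim = cfg.pre_s + np.arange(cfg.n_twitches) / cfg.pacing_hz
    d = np.full_like(t, cfg.baseline_deflection)
    amp_um = cfg.twitch_force / cfg.spring_constant
    for s in stim:
        d += amp_um * ghat(t - s)
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_sd > 0:
        d = d + rng.normal(0.0, cfg.noise_sd, d.shape)
    return Trace(d, cfg.sampling_rate, kind="deflection", stim_times=stim), cfg.twitch_force
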