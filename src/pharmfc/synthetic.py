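"""Synthetic multi-animal BOLD generator with known ground truth.

Emulates the study design the analysis modules are built for: an 80-min
resting-state run at TR = 1 s (4800 samples) per animal, 7 wild-type (WT)
and 7 receptor-knockout (KO) animals, a vehicle (saline) injection at
minute 20 and a drug (amylin) injection at minute 50. The responder
genotype (WT) carries transient drug-evoked connectivity changes on a
configured set of edges and a drug-evoked low-frequency power gain;
both genotypes carry injection-common artifacts after BOTH injections.

Signals are built from a latent block-factor model with time-varying
loadings: each ROI mixes a community factor, a global factor, optional
edge-specific factors (whose loadings follow the drug / artifact
envelopes) and private noise, with the private-noise loading chosen so
the stochastic core keeps exactly unit marginal variance. Because the
covariance is a Gram matrix of loadings at every sample, it is positive
semi-definite along the whole time-varying path by construction, and
the pairwise correlation of edge (i, j) equals ``base_ij + delta_ij(t)``
exactly. Band-limited oscillators are added on top of the unit-variance
core (so amplitude/power effects remain visible as SD changes); the
ground-truth object reports the resulting model-implied correlations.

Randomness uses one root seed with per-animal child streams; the same
streams feed both genotypes, so a KO animal is bit-identical to its WT
counterpart whenever no genotype-conditional effect is configured.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .containers import RoiTimeSeriesSet

# Slow-band edges in Hz (canonical low-frequency BOLD bands).
SLOW_BANDS: dict[str, tuple[float, float]] = {
    "slow-5": (0.01, 0.027),
    "slow-4": (0.027, 0.073),
    "slow-3": (0.073, 0.1),
}

# 30 atlas-style parcels grouped into four communities:
# hindbrain, hypothalamic/limbic, thalamic/insular, cortical/striatal.
DEFAULT_ROI_LABELS: list[str] = [
    "AP", "NTS", "PBN", "NLL", "PPN", "PRN", "IC", "CB",
    "ARC", "PVN", "LH", "VMN", "CeA", "NAc", "VTA", "LSN",
    "PVT", "AntT", "LatT", "VPT", "AIp", "Visc", "GP",
    "PL", "M1", "M2", "S1", "S2", "CPu", "RSv",
]

DEFAULT_BLOCK_SIZES = (8, 8, 7, 7)

# Drug-modulated edges (responder genotype only). ROI-disjoint so the
# per-ROI variance budget stays valid, and placed within communities:
# the Fisher-z transform amplifies shifts on edges with a non-trivial
# baseline correlation, which an analytic power model (n = 7, df = 6,
# 600-s intervals under the 0.008-0.1 Hz band, BH over all edges at
# q = 0.01) shows is required for the injected effects to be reliably
# discoverable. Signed deltas in correlation units.
DEFAULT_DRUG_EDGES: list[tuple[str, str, float]] = [
    ("AP", "PBN", -0.75),
    ("IC", "NLL", 0.70),
    ("LH", "CeA", 0.72),
    ("ARC", "PVN", 0.70),
    ("NAc", "VTA", 0.68),
    ("VMN", "LSN", -0.75),
    ("AIp", "AntT", 0.68),
    ("PVT", "LatT", 0.70),
]

# Injection-common artifact edges: perturbed for one 10-min interval after
# BOTH injections in BOTH genotypes (exercises the exclusion rule).
# Also within-community, for the same discoverability reason — a flagged
# artifact must first be significant in the mirrored vehicle contrast.
DEFAULT_ARTIFACT_EDGES: list[tuple[str, str, float]] = [
    ("M1", "S1", 0.55),
    ("M2", "S2", 0.55),
    ("CPu", "RSv", 0.55),
]


@dataclass(frozen=True)
class BlockCovarianceSpec:
    """Community structure of the baseline correlation matrix."""

    block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES
    within_r: float = 0.25
    between_r: float = 0.04

    def validate(self) -> None:
        if not 0.0 <= self.between_r < self.within_r < 1.0:
            raise ValueError("require 0 <= between_r < within_r < 1")


@dataclass(frozen=True)
class InjectionArtifactSpec:
    """Transient effects applied after BOTH injections in BOTH genotypes.

    A brief global amplitude transient (multiplicative, <= 120 s) plus a
    fixed set of spurious edge shifts lasting ``edge_duration_s`` after
    each injection.
    """

    edges: tuple[tuple[str, str, float], ...] = tuple(DEFAULT_ARTIFACT_EDGES)
    edge_duration_s: float = 600.0
    global_amplitude: float = 0.5
    global_tau_s: float = 40.0
    global_duration_s: float = 120.0

    def validate(self) -> None:
        if self.global_duration_s > 120.0 + 1e-9:
            raise ValueError("global amplitude transient must be <= 120 s")


@dataclass(frozen=True)
class OscillatorSpec:
    """Band-limited stochastic oscillation added to a set of ROIs.

    ``gain`` maps (genotype, condition) to a multiplicative amplitude
    gain; unspecified combinations default to 1. Each target ROI gets an
    independent narrow-band series (no covariance is introduced), so the
    oscillator changes spectral content and variance but leaves the
    factor-model covariance untouched apart from variance attenuation.
    """

    band: str = "slow-5"
    center_hz: float = 0.02
    amplitude: float = 0.35
    halfwidth_hz: float = 0.007
    rois: tuple[str, ...] = ("NTS", "PPN", "PRN")
    gain: tuple[tuple[tuple[str, str], float], ...] = ((("WT", "drug"), 2.0),)

    def gain_for(self, genotype: str, condition: str) -> float:
        return dict(self.gain).get((genotype, condition), 1.0)

    def validate(self) -> None:
        if self.band not in SLOW_BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        lo, hi = SLOW_BANDS[self.band]
        if not lo <= self.center_hz <= hi:
            raise ValueError("center frequency outside its named band")


@dataclass(frozen=True)
class NuisanceSpec:
    """Structured non-neuronal contamination removable by preprocessing."""

    drift_order: int = 1
    drift_amplitude: float = 0.8     # SD of per-ROI polynomial drift coefs
    wmcsf_sd: float = 0.25           # SD of per-ROI pseudo-WM/CSF loadings
    spike_rate: float = 0.0          # expected spikes per sample per ROI
    spike_amplitude: float = 3.0


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort (the study conditions)."""

    n_animals_per_genotype: int = 7
    n_roi: int = 30
    tr_s: float = 1.0
    duration_s: float = 4800.0
    vehicle_onset_s: float = 1200.0
    drug_onset_s: float = 3000.0
    roi_labels: list[str] | None = None
    baseline_covariance_spec: BlockCovarianceSpec = field(default_factory=BlockCovarianceSpec)
    drug_effect_edges: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_DRUG_EDGES))
    drug_onset_tau_s: float = 120.0
    drug_decay_halflife_s: float = 780.0  # drug half-life of ~13 min
    injection_artifact_spec: InjectionArtifactSpec = field(default_factory=InjectionArtifactSpec)
    oscillator_spec: list[OscillatorSpec] = field(default_factory=lambda: [OscillatorSpec()])
    noise_sd: float = 0.0            # extra white measurement noise
    nuisance_spec: NuisanceSpec = field(default_factory=NuisanceSpec)
    seed: int = 0

    # -- derived layout ------------------------------------------------
    @property
    def n_t(self) -> int:
        return int(round(self.duration_s / self.tr_s))

    def labels(self) -> list[str]:
        if self.roi_labels is not None:
            return list(self.roi_labels)
        if self.n_roi == len(DEFAULT_ROI_LABELS):
            return list(DEFAULT_ROI_LABELS)
        return [f"ROI{i:02d}" for i in range(self.n_roi)]

    def block_of(self) -> np.ndarray:
        sizes = self.baseline_covariance_spec.block_sizes
        if sum(sizes) != self.n_roi:
            # fall back to near-equal blocks when n_roi deviates
            n_blocks = max(1, len(sizes))
            base = self.n_roi // n_blocks
            sizes = tuple(base + (1 if i < self.n_roi % n_blocks else 0)
                          for i in range(n_blocks))
        return np.repeat(np.arange(len(sizes)), sizes)

    def validate(self) -> None:
        if self.n_animals_per_genotype < 1 or self.n_roi < 2:
            raise ValueError("need >=1 animal per genotype and >=2 ROIs")
        if self.duration_s <= 0 or self.tr_s <= 0:
            raise ValueError("durations must be positive")
        if abs(self.duration_s / self.tr_s - round(self.duration_s / self.tr_s)) > 1e-9:
            raise ValueError("duration must be divisible by TR")
        if not 0 < self.vehicle_onset_s < self.drug_onset_s < self.duration_s:
            raise ValueError("onsets must be strictly increasing and < duration")
        self.baseline_covariance_spec.validate()
        self.injection_artifact_spec.validate()
        for osc in self.oscillator_spec:
            osc.validate()
        labels = self.labels()
        if len(labels) != self.n_roi:
            raise ValueError("roi_labels length must equal n_roi")
        for a, b, d in list(self.drug_effect_edges) + list(self.injection_artifact_spec.edges):
            if a not in labels or b not in labels or a == b:
                raise ValueError(f"bad edge ({a}, {b})")
            if not -1.0 < d < 1.0:
                raise ValueError("edge deltas must lie in (-1, 1)")
        # Variance budget: factor loadings + peak |delta| per ROI must not
        # exceed unit variance, otherwise the covariance path leaves the
        # PSD cone and the config is rejected.
        spec = self.baseline_covariance_spec
        peak = {lab: spec.within_r for lab in labels}
        for a, b, d in self.drug_effect_edges:
            peak[a] += abs(d)
            peak[b] += abs(d)
        for a, b, d in self.injection_artifact_spec.edges:
            peak[a] += abs(d)
            peak[b] += abs(d)
        worst = max(peak.values())
        if worst > 1.0:
            raise ValueError(
                f"non-PSD target covariance: per-ROI variance budget {worst:.3f} > 1; "
                "reduce within-block correlation or edge deltas")


def drug_envelope(t_s: np.ndarray | float, onset_s: float, tau_s: float,
                  halflife_s: float, peak_factor: float = 3.0) -> np.ndarray:
    """Normalized drug-effect envelope: 0 before onset, peak 1 at
    ``onset + peak_factor * tau``, then exact halving every ``halflife_s``.

    The rise is a saturating exponential with time constant ``tau_s``
    rescaled to reach 1 at the peak time; the decay is ``2**(-s/halflife)``
    from the peak, mirroring first-order pharmacokinetic clearance.
    """
    s = np.asarray(t_s, dtype=float) - onset_s
    t_pk = peak_factor * tau_s
    rise = (1.0 - np.exp(-np.clip(s, 0.0, None) / tau_s)) / (1.0 - np.exp(-t_pk / tau_s))
    decay = 0.5 ** (np.clip(s - t_pk, 0.0, None) / halflife_s)
    env = np.where(s <= 0, 0.0, np.where(s <= t_pk, rise, decay))
    return env


@dataclass
class SyntheticGroundTruth:
    """Everything a test needs to score recovery against the generator."""

    modulated_edges: list[tuple[tuple[str, str], float, float, float]]
    artifact_edges: list[tuple[str, str, float]]
    band_gain_table: dict[tuple[str, str, str], float]
    roi_labels: list[str]
    baseline_corr: np.ndarray
    config: SimulationConfig

    def modulated_pairs(self) -> list[tuple[str, str]]:
        return [edge for edge, *_ in self.modulated_edges]

    def artifact_pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _ in self.artifact_edges]

    def correlation_timecourse(self, roi_a: str, roi_b: str,
                               t_s: np.ndarray, genotype: str = "WT") -> np.ndarray:
        """Model-implied correlation of one edge over time.

        Combines the baseline block correlation, any drug / artifact delta
        active at each time point, and the variance attenuation from
        oscillators (nuisance terms are excluded: they are what the
        preprocessing stage removes).
        """
        cfg = self.config
        t_s = np.asarray(t_s, dtype=float)
        i = self.roi_labels.index(roi_a)
        j = self.roi_labels.index(roi_b)
        block = cfg.block_of()
        spec = cfg.baseline_covariance_spec
        base = spec.within_r if block[i] == block[j] else spec.between_r
        delta = np.zeros_like(t_s)
        for (a, b), d, onset, hl in self.modulated_edges:
            if {a, b} == {roi_a, roi_b} and genotype == "WT":
                delta = delta + d * drug_envelope(t_s, onset, cfg.drug_onset_tau_s, hl)
        art = cfg.injection_artifact_spec
        for a, b, d in self.artifact_edges:
            if {a, b} == {roi_a, roi_b}:
                for onset in (cfg.vehicle_onset_s, cfg.drug_onset_s):
                    active = (t_s >= onset) & (t_s < onset + art.edge_duration_s)
                    delta = delta + d * active
        var_i = 1.0 + _oscillator_variance(cfg, roi_a, t_s, genotype) + cfg.noise_sd ** 2
        var_j = 1.0 + _oscillator_variance(cfg, roi_b, t_s, genotype) + cfg.noise_sd ** 2
        return (base + delta) / np.sqrt(var_i * var_j)


def _condition_at(cfg: SimulationConfig, t_s: np.ndarray) -> np.ndarray:
    cond = np.full(t_s.shape, "baseline", dtype=object)
    cond[t_s >= cfg.vehicle_onset_s] = "vehicle"
    cond[t_s >= cfg.drug_onset_s] = "drug"
    return cond


def _oscillator_variance(cfg: SimulationConfig, roi: str, t_s: np.ndarray,
                         genotype: str) -> np.ndarray:
    v = np.zeros_like(np.asarray(t_s, dtype=float))
    cond = _condition_at(cfg, np.asarray(t_s, dtype=float))
    for osc in cfg.oscillator_spec:
        if roi in osc.rois:
            gains = np.array([osc.gain_for(genotype, c) for c in cond])
            v = v + (osc.amplitude * gains) ** 2
    return v


def _narrowband(rng: np.random.Generator, n_t: int, fs: float,
                center_hz: float, halfwidth_hz: float) -> np.ndarray:
    """Unit-SD narrow-band noise centred on ``center_hz``."""
    lo = max(1e-4, center_hz - halfwidth_hz)
    hi = min(0.49 * fs, center_hz + halfwidth_hz)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n_t))
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_series(rng: np.random.Generator, n_t: int, fs: float,
                   cutoff_hz: float = 0.05) -> np.ndarray:
    sos = sps.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n_t))
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_cohort(config: SimulationConfig) -> tuple[RoiTimeSeriesSet, SyntheticGroundTruth]:
    """Generate the two-genotype cohort and its ground truth.

    Returns one ROI x time matrix per animal (WT animals first), each of
    ``duration_s / tr_s`` samples, plus a :class:`SyntheticGroundTruth`
    recording the modulated edges, artifact edges and band-gain table.
    Identical seeds give bit-identical output.
    """
    config.validate()
    labels = config.labels()
    n_t, fs = config.n_t, 1.0 / config.tr_s
    t_s = np.arange(n_t) * config.tr_s
    block = config.block_of()
    n_blocks = int(block.max()) + 1
    spec = config.baseline_covariance_spec
    a = np.sqrt(spec.within_r - spec.between_r)   # block-factor loading
    c = np.sqrt(spec.between_r)                   # global-factor loading
    lab_idx = {lab: k for k, lab in enumerate(labels)}
    art = config.injection_artifact_spec

    # Per-edge signed delta envelopes, per genotype.
    def edge_deltas(genotype: str) -> list[tuple[int, int, np.ndarray]]:
        out = []
        for aa, bb, d in config.drug_effect_edges:
            env = d * drug_envelope(t_s, config.drug_onset_s,
                                    config.drug_onset_tau_s,
                                    config.drug_decay_halflife_s)
            if genotype != "WT":
                env = np.zeros_like(env)
            out.append((lab_idx[aa], lab_idx[bb], env))
        for aa, bb, d in art.edges:
            env = np.zeros(n_t)
            for onset in (config.vehicle_onset_s, config.drug_onset_s):
                env += d * ((t_s >= onset) & (t_s < onset + art.edge_duration_s))
            out.append((lab_idx[aa], lab_idx[bb], env))
        return out

    # Global amplitude transient after each injection (both genotypes).
    gamp = np.zeros(n_t)
    for onset in (config.vehicle_onset_s, config.drug_onset_s):
        s = t_s - onset
        active = (s >= 0) & (s < art.global_duration_s)
        gamp += np.where(active, art.global_amplitude * np.exp(-s / art.global_tau_s), 0.0)

    cond = _condition_at(config, t_s)
    nui = config.nuisance_spec
    n_edge_factors = len(config.drug_effect_edges) + len(art.edges)

    data = np.empty((2 * config.n_animals_per_genotype, config.n_roi, n_t))
    nuisance = np.empty((2 * config.n_animals_per_genotype, 2, n_t))
    ids, genos = [], []

    children = np.random.SeedSequence(config.seed).spawn(config.n_animals_per_genotype)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        # One draw per animal index, shared by both genotypes so the KO
        # cohort is distribution- (and bit-) identical except where a
        # genotype-conditional effect is configured.
        F = rng.standard_normal((n_blocks, n_t))
        G = rng.standard_normal(n_t)
        U = rng.standard_normal((n_edge_factors, n_t))
        E = rng.standard_normal((config.n_roi, n_t))
        osc_series = [
            np.stack([_narrowband(rng, n_t, fs, osc.center_hz, osc.halfwidth_hz)
                      for _ in osc.rois])
            for osc in config.oscillator_spec
        ]
        wm = _smooth_series(rng, n_t, fs)
        csf = _smooth_series(rng, n_t, fs)
        wm_load = rng.normal(0.0, nui.wmcsf_sd, config.n_roi)
        csf_load = rng.normal(0.0, nui.wmcsf_sd, config.n_roi)
        drift_coef = rng.normal(0.0, nui.drift_amplitude,
                                (config.n_roi, max(nui.drift_order, 0)))
        meas = rng.standard_normal((config.n_roi, n_t)) if config.noise_sd > 0 else None
        spikes = None
        if nui.spike_rate > 0:
            spikes = (rng.random((config.n_roi, n_t)) < nui.spike_rate) * \
                rng.normal(0.0, nui.spike_amplitude, (config.n_roi, n_t))

        for g_idx, genotype in enumerate(("WT", "KO")):
            deltas = edge_deltas(genotype)
            used = np.zeros((config.n_roi, n_t))  # per-ROI |delta| budget
            x = a * F[block] + c * G[None, :]
            for k, (ii, jj, env) in enumerate(deltas):
                mag = np.sqrt(np.abs(env))
                x[ii] += mag * U[k]
                x[jj] += np.sign(env) * mag * U[k]
                used[ii] += np.abs(env)
                used[jj] += np.abs(env)
            resid_var = 1.0 - a * a - c * c - used
            if resid_var.min() < -1e-9:
                raise ValueError("non-PSD target covariance at runtime")
            x += np.sqrt(np.clip(resid_var, 0.0, None)) * E
            # band-limited oscillators (added on top of the unit core)
            for osc, series in zip(config.oscillator_spec, osc_series):
                gains = np.array([osc.gain_for(genotype, cc) for cc in cond])
                for r, lab in enumerate(osc.rois):
                    x[lab_idx[lab]] += osc.amplitude * gains * series[r]
            # injection-common global amplitude transient
            x = x * (1.0 + gamp)[None, :]
            # nuisance: polynomial drift, pseudo-WM/CSF, spikes, sensor noise
            tt = np.linspace(-1.0, 1.0, n_t)
            for p in range(nui.drift_order):
                x += drift_coef[:, p][:, None] * tt[None, :] ** (p + 1)
            x += wm_load[:, None] * wm[None, :] + csf_load[:, None] * csf[None, :]
            if spikes is not None:
                x += spikes
            if meas is not None:
                x += config.noise_sd * meas
            row = g_idx * config.n_animals_per_genotype + i
            data[row] = x
            nuisance[row, 0] = wm
            nuisance[row, 1] = csf
    for genotype in ("WT", "KO"):
        for i in range(config.n_animals_per_genotype):
            ids.append(f"{genotype}{i + 1:02d}")
            genos.append(genotype)

    tsset = RoiTimeSeriesSet(
        data=data, animal_ids=ids, genotypes=genos, roi_labels=labels,
        tr_s=config.tr_s, vehicle_onset_s=config.vehicle_onset_s,
        drug_onset_s=config.drug_onset_s, nuisance=nuisance)

    base = np.full((config.n_roi, config.n_roi), spec.between_r)
    same = block[:, None] == block[None, :]
    base[same] = spec.within_r
    np.fill_diagonal(base, 1.0)
    v0 = np.array([
        _oscillator_variance(config, lab, np.array([0.0]), "WT")[0] for lab in labels
    ]) + config.noise_sd ** 2
    atten = 1.0 / np.sqrt(1.0 + v0)
    baseline_corr = base * atten[:, None] * atten[None, :]
    np.fill_diagonal(baseline_corr, 1.0)

    band_gain = {}
    for osc in config.oscillator_spec:
        for (genotype, condition), g in osc.gain:
            band_gain[(genotype, condition, osc.band)] = g
    gt = SyntheticGroundTruth(
        modulated_edges=[((aa, bb), d, config.drug_onset_s, config.drug_decay_halflife_s)
                         for aa, bb, d in config.drug_effect_edges],
        artifact_edges=list(art.edges),
        band_gain_table=band_gain,
        roi_labels=labels,
        baseline_corr=baseline_corr,
        config=config,
    )
    return tsset, gt


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _sidecar(tsset: RoiTimeSeriesSet, files: dict[str, str]) -> dict:
    return {
        "tr_s": tsset.tr_s,
        "duration_s": tsset.duration_s,
        "vehicle_onset_s": tsset.vehicle_onset_s,
        "drug_onset_s": tsset.drug_onset_s,
        "roi_labels": list(tsset.roi_labels),
        "animals": [
            {"id": aid, "genotype": g, "file": files[aid]}
            for aid, g in zip(tsset.animal_ids, tsset.genotypes)
        ],
    }


def export_cohort(tsset: RoiTimeSeriesSet, path: str | Path,
                  format: str = "table") -> list[Path]:
    """Write the cohort to disk.

    ``table``: one TSV per animal (rows = time, columns = ROI, header =
    ROI labels) plus a ``cohort.json`` timing/metadata sidecar.
    ``volume``: one 4D NIfTI per animal with each ROI occupying a distinct
    voxel, plus an integer label atlas (``atlas.nii``) and the sidecar;
    round-trip extraction recovers the tables within float tolerance.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    files: dict[str, str] = {}
    if format == "table":
        for k, aid in enumerate(tsset.animal_ids):
            f = path / f"{aid}.tsv"
            header = "\t".join(tsset.roi_labels)
            np.savetxt(f, tsset.data[k].T, fmt="%.10g", delimiter="\t",
                       header=header, comments="")
            files[aid] = f.name
            written.append(f)
    elif format == "volume":
        import nibabel as nib

        affine = np.eye(4)
        atlas = np.arange(1, tsset.n_roi + 1, dtype=np.int16).reshape(-1, 1, 1)
        atlas_f = path / "atlas.nii"
        nib.save(nib.Nifti1Image(atlas, affine), atlas_f)
        written.append(atlas_f)
        for k, aid in enumerate(tsset.animal_ids):
            f = path / f"{aid}.nii"
            vol = tsset.data[k].reshape(tsset.n_roi, 1, 1, tsset.n_t).astype(np.float32)
            nib.save(nib.Nifti1Image(vol, affine), f)
            files[aid] = f.name
            written.append(f)
    else:
        raise ValueError(f"unsupported export format {format!r}")
    sidecar = path / "cohort.json"
    sidecar.write_text(json.dumps(_sidecar(tsset, files), indent=1))
    written.append(sidecar)
    return written
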