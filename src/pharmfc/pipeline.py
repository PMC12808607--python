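"""End-to-end orchestration: config, run bundle, manifest.

``run_pipeline`` sequences the full analysis — input (simulate / tables /
volumes), temporal preprocessing, condition segmentation, interval FC,
difference maps, FC variability, global dynamic FC, the drug edge
contrast with injection-artifact exclusion, and group ICA with slow-band
spectral statistics — and writes a deterministic CSV/JSON bundle plus a
run manifest (config hash, seed, package versions). Identical config and
seed reproduce the bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from . import dynamic_fc, edge_stats, io, spectra, static_fc, synthetic
from .containers import CONDITIONS

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TimingBlock(_Block):
    tr_s: float = 1.0
    duration_s: float = 4800.0
    vehicle_onset_s: float = 1200.0
    drug_onset_s: float = 3000.0
    interval_length_s: float = 600.0


class PreprocessingBlock(_Block):
    band_hz: tuple[float, float] | None = (0.008, 0.1)
    detrend_order: int = 1
    filter_order: int = 4
    use_nuisance: bool = True


class WindowBlock(_Block):
    window_length_s: float = 300.0
    step_samples: int = 1


class ContrastBlock(_Block):
    alpha: float = 0.01            # edge-discovery FDR threshold
    report_alpha: float = 0.05     # secondary threshold, also reported
    artifact_exclusion: bool = True


class IcaBlock(_Block):
    enabled: bool = True
    n_components: int = 20
    welch_segment_s: float = 256.0
    overlap: float = 0.5
    band: str = "slow-5"


class SimulationBlock(_Block):
    n_animals_per_genotype: int = 7
    n_roi: int = 30
    noise_sd: float = 0.0


class PipelineConfig(_Block):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    mode: Literal["simulate", "tables", "volumes"] = "simulate"
    input_path: Optional[str] = None
    output_dir: str = "pharmfc_out"
    seed: int = 0
    timing: TimingBlock = Field(default_factory=TimingBlock)
    preprocessing: PreprocessingBlock = Field(default_factory=PreprocessingBlock)
    window: WindowBlock = Field(default_factory=WindowBlock)
    contrast: ContrastBlock = Field(default_factory=ContrastBlock)
    ica: IcaBlock = Field(default_factory=IcaBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _simulation_config(cfg: PipelineConfig) -> synthetic.SimulationConfig:
    return synthetic.SimulationConfig(
        n_animals_per_genotype=cfg.simulation.n_animals_per_genotype,
        n_roi=cfg.simulation.n_roi,
        tr_s=cfg.timing.tr_s,
        duration_s=cfg.timing.duration_s,
        vehicle_onset_s=cfg.timing.vehicle_onset_s,
        drug_onset_s=cfg.timing.drug_onset_s,
        noise_sd=cfg.simulation.noise_sd,
        seed=cfg.seed,
    )


def _load_input(cfg: PipelineConfig):
    if cfg.mode == "simulate":
        tsset, gt = synthetic.simulate_cohort(_simulation_config(cfg))
        return tsset, gt
    if cfg.input_path is None:
        raise ValueError(f"mode {cfg.mode!r} requires input_path")
    if cfg.mode == "tables":
        return io.load_cohort_tables(cfg.input_path), None
    return io.load_cohort_volumes(cfg.input_path), None


def _write_matrix(path: Path, mat: np.ndarray, labels: list[str]) -> None:
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(
        path, float_format=_FLOAT_FMT)


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-18s %6.2f s", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a result summary dict.

    Writes per run: interval FC matrices, difference matrices, FC
    variability, global-FC series, edge-contrast tables (with artifact
    flags and significant-edge lists), ICA maps and slow-band powers,
    and ``manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    result: dict = {"output_dir": str(out)}

    tsset, gt = _load_input(config)
    t0 = _stage("input", t0)

    pre = io.preprocess(
        tsset,
        nuisance="auto" if config.preprocessing.use_nuisance else None,
        band=config.preprocessing.band_hz,
        detrend_order=config.preprocessing.detrend_order,
        filter_order=config.preprocessing.filter_order)
    seg = io.segment_conditions(pre, config.timing.interval_length_s)
    result["interval_counts"] = seg.counts()
    t0 = _stage("preprocess", t0)

    labels = pre.roi_labels
    zstack = static_fc.interval_fc(pre, seg, space="z")
    genotypes = sorted(set(pre.genotypes))
    fcdir = out / "fc"
    fcdir.mkdir(exist_ok=True)
    for genotype in genotypes:
        mask = np.array([g == genotype for g in pre.genotypes])
        for m, iv in enumerate(seg):
            mean_z = static_fc.group_mean_fc(zstack[mask, m], "z").values
            _write_matrix(fcdir / f"mean_z_{genotype}_{iv.condition}{iv.index + 1}.csv",
                          mean_z, labels)
            if m > 0:
                prev = static_fc.group_mean_fc(zstack[mask, m - 1], "z").values
                _write_matrix(
                    fcdir / f"diff_z_{genotype}_{m:02d}_minus_{m - 1:02d}.csv",
                    mean_z - prev, labels)
    if len(genotypes) == 2:
        base_idx = [m for m, iv in enumerate(seg) if iv.condition == "baseline"]
        groups = {}
        for genotype in genotypes:
            mask = np.array([g == genotype for g in pre.genotypes])
            groups[genotype] = [static_fc.FcMatrix(zstack[k, m], "z")
                                for k in np.flatnonzero(mask) for m in base_idx]
        contrast = static_fc.genotype_baseline_contrast(
            groups.get("WT", []), groups.get("KO", []))
        _write_matrix(out / "baseline_contrast_KO_minus_WT.csv",
                      contrast.values, labels)
    var_table = static_fc.fc_variability_table(pre, zstack, seg)
    var_table.to_csv(out / "fc_variability.csv", index=False,
                     float_format=_FLOAT_FMT)
    result["fc_variability"] = {
        (g, c): float(var_table.query("genotype == @g and condition == @c")
                      ["variability"].mean())
        for g in genotypes for c in CONDITIONS}
    t0 = _stage("static_fc", t0)

    for genotype in genotypes:
        sub = pre.subset(genotype)
        _, mean_g, sem_g = dynamic_fc.global_fc_timecourses(
            sub, config.window.window_length_s, config.window.step_samples)
        grid = np.arange(mean_g.shape[1]) * config.window.step_samples * pre.tr_s
        df = pd.DataFrame(mean_g, index=labels, columns=grid)
        df.to_csv(out / f"global_fc_mean_{genotype}.csv", float_format="%.6g")
        pd.DataFrame(sem_g, index=labels, columns=grid).to_csv(
            out / f"global_fc_sem_{genotype}.csv", float_format="%.6g")
        result.setdefault("n_windows", mean_g.shape[1])
    t0 = _stage("dynamic_fc", t0)

    sig_counts = {}
    for genotype in genotypes:
        mask = np.array([g == genotype for g in pre.genotypes])
        zg = zstack[mask]
        x, y, pairs = edge_stats.amylin_contrast_values(zg, seg, labels)
        drug_tab = edge_stats.edge_contrast_table(
            x, y, pairs, alpha=config.contrast.alpha, contrast="drug")
        if config.contrast.artifact_exclusion:
            xv, yv, _ = edge_stats.vehicle_mirror_contrast_values(zg, seg, labels)
            veh_tab = edge_stats.edge_contrast_table(
                xv, yv, pairs, alpha=config.contrast.alpha, contrast="vehicle-mirror")
            drug_tab = edge_stats.flag_injection_artifacts(veh_tab, drug_tab)
            edge_stats.export_edges(veh_tab, out / f"edges_{genotype}_vehicle_mirror")
        edge_stats.export_edges(drug_tab, out / f"edges_{genotype}")
        sig_counts[genotype] = int(drug_tab.df["significant"].sum())
    result["significant_edges"] = sig_counts
    t0 = _stage("edge_stats", t0)

    if config.ica.enabled:
        cs = spectra.group_ica(pre, n_comp=config.ica.n_components,
                               seed=config.seed)
        excluded = spectra.flag_components(cs, tsset.nuisance)
        pd.DataFrame(cs.spatial_maps, index=cs.component_labels,
                     columns=labels).to_csv(out / "ica_spatial_maps.csv",
                                            float_format=_FLOAT_FMT)
        amp_rows, bp_frames = [], []
        keep = [k for k in range(cs.n_comp) if k not in excluded]
        for k in keep[: min(4, len(keep))]:
            for a in range(pre.n_animals):
                amps = spectra.condition_amplitude(cs.time_courses[a, k], seg)
                amp_rows.append({"component": cs.component_labels[k],
                                 "animal": pre.animal_ids[a],
                                 "genotype": pre.genotypes[a], **amps})
            bp = spectra.band_power_contrast(
                pre, seg, cs.time_courses[:, k, :], band=config.ica.band,
                segment_length_s=config.ica.welch_segment_s,
                overlap=config.ica.overlap)
            bp.insert(0, "component", cs.component_labels[k])
            bp_frames.append(bp)
        pd.DataFrame(amp_rows).to_csv(out / "component_amplitudes.csv",
                                      index=False, float_format=_FLOAT_FMT)
        if bp_frames:
            pd.concat(bp_frames, ignore_index=True).to_csv(
                out / "band_power_contrast.csv", index=False,
                float_format=_FLOAT_FMT)
        result["ica"] = {"n_components": cs.n_comp,
                         "excluded_components": excluded}
        t0 = _stage("ica_spectra", t0)

    manifest = {
        "config": config.model_dump(mode="json"),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "interval_counts": result["interval_counts"],
        "significant_edges": sig_counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    result["manifest"] = manifest
    return result


def _versions() -> dict[str, str]:
    import numpy, pandas, scipy, sklearn  # noqa: PLC0415

    return {"pharmfc": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__,
            "scikit-learn": sklearn.__version__}


def render_report(bundle_dir: str | Path) -> str:
    """Plain-text summary of a run bundle (edge tables + band powers)."""
    bundle = Path(bundle_dir)
    manifest = json.loads((bundle / "manifest.json").read_text())
    lines = [
        "pharmfc run report",
        f"  config hash : {manifest['config_hash']}",
        f"  seed        : {manifest['seed']}",
        f"  intervals   : {manifest['interval_counts']}",
    ]
    for genotype, n in manifest["significant_edges"].items():
        lines.append(f"  {genotype}: {n} significant drug-contrast edge(s)")
        sig = bundle / f"edges_{genotype}" / "significant_edges.csv"
        if sig.exists():
            df = pd.read_csv(sig)
            for _, row in df.iterrows():
                lines.append(f"      {row['source']} - {row['target']} "
                             f"({row['direction']}, p_fdr={row['p_fdr']:.2g})")
    bp = bundle / "band_power_contrast.csv"
    if bp.exists():
        lines.append("  slow-band power (vehicle vs drug):")
        for _, row in pd.read_csv(bp).iterrows():
            lines.append(
                f"      {row['component']} {row['genotype']} {row['band']}: "
                f"{row['vehicle_mean']:.3g} -> {row['drug_mean']:.3g} "
                f"(t={row['t_stat']:.2f}, p={row['p']:.3g})")
    return "\n".join(lines)
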