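"""Pipeline orchestration: configuration, stage sequencing, reporting.

Ties the stages into the end-to-end analysis: simulate (or load) a cohort,
preprocess, voxel-wise GLM with per-subject FDR, regionalization and
event-related averaging, and the differential functional-connectivity
network procedure. Every analysis parameter defaults to the reference
protocol's value; all randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import glm as glm_mod
from . import preprocess as pre
from . import regional as reg
from . import synthetic as syn
from .paradigm import HRFParams, Paradigm, build_costim_paradigm, design_matrix

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "report"]


@dataclass
class RunConfig:
    """Full run configuration with protocol defaults.

    Serializes losslessly to/from YAML. The synthetic-cohort block defines
    the study conditions the pipeline is exercised under; the analysis
    block mirrors the reference protocol (FDR q = 0.05 per subject,
    activation-probability region selection at 0.5, 500 edges per
    correlation channel, homoscedastic two-tailed t tests at alpha 0.05).
    """

    seed: int = 0
    # paradigm (co-stimulation protocol)
    n_heat: int = 16
    interval_s: float = 100.0
    stim_duration_s: float = 20.0
    ramp_s: float = 5.0
    tr_s: float = 4.0
    n_volumes: int = 975
    # synthetic cohort
    grid_shape: tuple[int, int, int] = (16, 16, 8)
    n_regions: int = 20
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(syn.DEFAULT_GROUP_SIZES)
    )
    control_group: str = "control"
    treated_group: str = "activated"
    amplitudes: dict = field(default_factory=dict)
    group_multipliers: dict = field(default_factory=dict)
    couplings: list = field(default_factory=list)
    noise_sd: float = 0.2
    activation_probability: dict = field(default_factory=dict)
    # preprocessing
    discard_volumes: int = 0
    pairwise_resample: bool = False
    spatial_fwhm_vox: float = 2.0
    highpass_cycles: int = 9
    temporal_fwhm_s: float = 12.0
    # GLM / selection
    fdr_q: float = 0.05
    selection_threshold: float = 0.5
    # ERA
    era_pre: int = 10
    era_post: int = 15
    era_alpha: float = 0.05
    # connectivity
    n_pos: int = 500
    n_neg: int = 500
    fc_test: str = "homoscedastic"
    fc_alpha: float = 0.05
    display_threshold: int = 0
    composite_membership: dict = field(default_factory=dict)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- derived objects ----------------------------------------------------
    def build_paradigm(self) -> Paradigm:
        return build_costim_paradigm(
            n_heat=self.n_heat,
            interval=self.interval_s,
            stim_duration=self.stim_duration_s,
            ramp=self.ramp_s,
            tr=self.tr_s,
            n_volumes=self.n_volumes,
        )

    def build_effect_spec(self) -> syn.EffectSpec:
        couplings = tuple(
            c
            if isinstance(c, syn.CouplingSpec)
            else syn.CouplingSpec(
                region_a=int(c["region_a"]),
                region_b=int(c["region_b"]),
                channel=c["channel"],
                strength={k: float(v) for k, v in c["strength"].items()},
            )
            for c in self.couplings
        )
        return syn.EffectSpec(
            amplitudes={
                int(r): {k: float(v) for k, v in conds.items()}
                for r, conds in self.amplitudes.items()
            },
            group_multipliers=self.group_multipliers,
            couplings=couplings,
            noise_sd=self.noise_sd,
            activation_probability={
                int(r): float(p) for r, p in self.activation_probability.items()
            },
        )

    def membership(self, region_ids) -> dict[int, str]:
        if self.composite_membership:
            return {int(r): str(c) for r, c in self.composite_membership.items()}
        return {int(r): f"region_{int(r):03d}" for r in region_ids}


@dataclass
class PipelineResult:
    """End-to-end result bundle."""

    config: RunConfig
    paradigm: Paradigm
    atlas: syn.AtlasLabels
    cohort: syn.Cohort
    timecourses: dict  # subject -> {condition: RegionTimecourses}
    era: dict  # group -> list[ERAProfile]
    era_stats: pd.DataFrame
    selected_regions: list[int]
    subject_fc: dict  # condition -> {group: [FCMatrix]}
    group_fc: dict  # condition -> {group: FCMatrix}
    thresholded: dict  # condition -> {group: ThresholdedFC}
    diff: dict  # condition -> DiffFCMatrix
    networks: dict  # condition -> CompositeNetwork

    def checksum(self) -> str:
        """Digest over the quantitative outputs, for determinism checks."""
        h = hashlib.sha256()
        h.update(self.cohort.checksum().encode())
        for cond in sorted(self.networks):
            h.update(self.networks[cond].net.to_csv().encode())
        if len(self.era_stats):
            h.update(self.era_stats.round(12).to_csv().encode())
        return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, subject: str | None, cause: Exception):
        self.stage, self.subject = stage, subject
        where = f"stage {stage!r}"
        if subject:
            where += f", subject {subject!r}"
        super().__init__(f"{where}: {cause}")


def _preprocess_subject(
    sub: syn.SubjectData, paradigm: Paradigm, cfg: RunConfig
) -> tuple[pre.VolumeSeries, Paradigm]:
    series = sub.series
    if cfg.discard_volumes:
        series, paradigm = pre.discard_initial(
            series, cfg.discard_volumes, paradigm
        )
    if cfg.pairwise_resample:
        series = pre.pairwise_average(series)
        paradigm = paradigm.with_timing(series.tr, series.n_volumes)
    series = pre.spatial_smooth(series, cfg.spatial_fwhm_vox)
    series = pre.to_percent_change(series, paradigm)
    series = pre.temporal_filter(
        series, cfg.highpass_cycles, cfg.temporal_fwhm_s
    )
    return series, paradigm


def run_pipeline(cfg: RunConfig, rundir=None) -> PipelineResult:
    """Execute simulate -> preprocess -> GLM -> regionalize -> ERA -> FC
    -> differential networks; deterministic given the config seed.

    When ``rundir`` is given, all intermediates are written there
    (NIfTI volumes, TSV tables, GraphML networks, YAML/JSON provenance).
    """
    paradigm = cfg.build_paradigm()
    atlas = syn.make_atlas(cfg.grid_shape, cfg.n_regions, seed=cfg.seed)
    spec = cfg.build_effect_spec()
    try:
        cohort = syn.simulate_cohort(
            paradigm, atlas, spec, cfg.group_sizes, seed=cfg.seed
        )
    except Exception as e:  # pragma: no cover - defensive
        raise StageError("simulate", None, e) from e

    conditions = list(paradigm.kinds)
    timecourses: dict[str, dict[str, reg.RegionTimecourses]] = {}
    flags_rows = []
    eff_paradigm = paradigm
    for sub in cohort.subjects:
        try:
            series, eff_paradigm = _preprocess_subject(sub, paradigm, cfg)
            design = design_matrix(eff_paradigm)
            fit = glm_mod.fit_glm(series, design)
            per_cond = {}
            for cond in conditions:
                mask = glm_mod.activation_mask(
                    fit, cond, cfg.fdr_q, brain_mask=atlas.labels > 0
                )
                tc = reg.region_timecourses(
                    series, mask, atlas, predictor=cond,
                    units="percent", subject=sub.subject,
                )
                per_cond[cond] = tc
                flags_rows.append(
                    {
                        "entry": f"{sub.subject}:{cond}",
                        **{
                            int(r): (int(r) in tc.data.index)
                            for r in atlas.region_ids
                        },
                    }
                )
            timecourses[sub.subject] = per_cond
        except Exception as e:
            raise StageError("subject-analysis", sub.subject, e) from e

    flags = pd.DataFrame(flags_rows).set_index("entry")
    selected = reg.activation_probability(flags, cfg.selection_threshold)

    # event-related averages for the co-stimulation condition
    era: dict[str, list[reg.ERAProfile]] = {g: [] for g in cohort.groups}
    era_cond = "costim" if "costim" in conditions else conditions[0]
    for g, subs in cohort.groups.items():
        for sub in subs:
            tc = timecourses[sub.subject][era_cond]
            if len(tc.data):
                era[g].append(
                    reg.event_related_average(
                        tc, eff_paradigm, era_cond, cfg.era_pre, cfg.era_post
                    )
                )
    try:
        if (
            len(era.get(cfg.control_group, [])) >= 2
            and len(era.get(cfg.treated_group, [])) >= 2
        ):
            era_stats = reg.compare_era_groups(
                era[cfg.control_group],
                era[cfg.treated_group],
                alpha=cfg.era_alpha,
                label_a=cfg.control_group,
                label_b=cfg.treated_group,
            )
        else:
            era_stats = pd.DataFrame()
    except Exception as e:
        raise StageError("era", None, e) from e

    # functional connectivity per condition
    all_regions = [int(r) for r in atlas.region_ids]
    subject_fc: dict[str, dict[str, list[conn.FCMatrix]]] = {}
    group_fc: dict[str, dict[str, conn.FCMatrix]] = {}
    thresholded: dict[str, dict[str, conn.ThresholdedFC]] = {}
    diffs: dict[str, conn.DiffFCMatrix] = {}
    networks: dict[str, conn.CompositeNetwork] = {}
    fc_regions = selected if selected else all_regions
    membership = cfg.membership(all_regions)
    for cond in conditions:
        try:
            subject_fc[cond] = {}
            for g, subs in cohort.groups.items():
                mats = []
                for sub in subs:
                    tc = timecourses[sub.subject][cond]
                    data = tc.data.reindex(all_regions)
                    tc_full = reg.RegionTimecourses(
                        data=data, n_active=tc.n_active, tr=tc.tr,
                        subject=tc.subject, units=tc.units,
                    )
                    if data.notna().any(axis=1).sum() >= 2:
                        tc_full = conn.remove_global_mean(tc_full)
                    mats.append(conn.fc_matrix(tc_full))
                subject_fc[cond][g] = mats
            group_fc[cond] = {
                g: conn.group_mean_fc(m) for g, m in subject_fc[cond].items()
            }
            thresholded[cond] = {
                g: conn.threshold_fc(
                    group_fc[cond][g], fc_regions, cfg.n_pos, cfg.n_neg
                )
                for g in group_fc[cond]
            }
            diffs[cond] = conn.diff_fc(
                subject_fc[cond][cfg.control_group],
                subject_fc[cond][cfg.treated_group],
                edge_universe=(
                    thresholded[cond][cfg.control_group],
                    thresholded[cond][cfg.treated_group],
                ),
                test=cfg.fc_test,
                alpha=cfg.fc_alpha,
            )
            networks[cond] = conn.aggregate_composite(
                diffs[cond], membership, cfg.display_threshold
            )
        except Exception as e:
            raise StageError(f"connectivity:{cond}", None, e) from e

    result = PipelineResult(
        config=cfg,
        paradigm=eff_paradigm,
        atlas=atlas,
        cohort=cohort,
        timecourses=timecourses,
        era=era,
        era_stats=era_stats,
        selected_regions=selected,
        subject_fc=subject_fc,
        group_fc=group_fc,
        thresholded=thresholded,
        diff=diffs,
        networks=networks,
    )
    if rundir is not None:
        write_bundle(result, rundir)
    return result


def write_bundle(result: PipelineResult, rundir) -> None:
    """Write all intermediates and outputs in standard formats."""
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    cfg.to_yaml(rundir / "config.yaml")
    result.paradigm.to_tsv(rundir / "paradigm.tsv")
    syn.cohort_manifest(result.cohort).to_csv(
        rundir / "cohort.tsv", sep="\t", index=False
    )
    import nibabel as nib

    aff = np.diag([0.234] * 3 + [1.0])
    nib.Nifti1Image(result.atlas.labels.astype(np.int16), aff).to_filename(
        str(rundir / "atlas_labels.nii")
    )
    tcdir = rundir / "timecourses"
    tcdir.mkdir(exist_ok=True)
    for sub, per_cond in result.timecourses.items():
        for cond, tc in per_cond.items():
            tc.to_tsv(tcdir / f"{sub}_{cond}.tsv")
    if len(result.era_stats):
        result.era_stats.to_csv(rundir / "era_group_stats.tsv", sep="\t")
    (rundir / "selected_regions.json").write_text(
        json.dumps(result.selected_regions)
    )
    fcdir = rundir / "fc"
    fcdir.mkdir(exist_ok=True)
    for cond, per_group in result.group_fc.items():
        for g, m in per_group.items():
            m.to_tsv(fcdir / f"group_mean_{cond}_{g}.tsv")
    for cond, net in result.networks.items():
        net.to_edgelist().to_csv(
            rundir / f"network_{cond}.tsv", sep="\t", index=False
        )
        net.to_graphml(rundir / f"network_{cond}.graphml")
        result.diff[cond].indicators["positive"].add(
            result.diff[cond].indicators["negative"]
        ).to_csv(rundir / f"netfc_{cond}.tsv", sep="\t")
    (rundir / "report.txt").write_text(report(result))


def report(result: PipelineResult) -> str:
    """Human-readable summary: ERA group differences, net-FC per condition,
    displayed composite edges."""
    lines = ["stimfc run report", "=" * 40]
    cfg = result.config
    lines.append(
        f"cohort: {sum(cfg.group_sizes.values())} subjects "
        f"({', '.join(f'{g}={n}' for g, n in sorted(cfg.group_sizes.items()))}), "
        f"seed {cfg.seed}"
    )
    lines.append(
        f"paradigm: {len(result.paradigm.events)} events, "
        f"TR {result.paradigm.tr:g} s, {result.paradigm.n_volumes} volumes"
    )
    lines.append(
        f"selected regions (activation probability >= "
        f"{cfg.selection_threshold:g}): {len(result.selected_regions)}"
    )
    lines.append("")
    lines.append("ERA group comparison (Bonferroni-corrected):")
    if len(result.era_stats):
        sig = result.era_stats[result.era_stats["significant"]]
        if len(sig):
            for rid, row in sig.iterrows():
                lines.append(
                    f"  region {rid}: {row.direction} "
                    f"(diff {row.diff_mean:+.3f} +/- {row.sem_diff:.3f} %, "
                    f"p_bonf={row.p_bonf:.4g})"
                )
        else:
            lines.append("  no region significant")
    else:
        lines.append("  not computed (insufficient groups)")
    for cond, net in result.networks.items():
        edges = net.edges()
        lines.append("")
        lines.append(
            f"differential FC network [{cond}] "
            f"(|net FC| > {net.display_threshold}):"
        )
        if not edges:
            lines.append("  zero significant edges")
        for e in edges:
            arrow = {"ab": "->", "ba": "<-", "both": "<->"}.get(
                e["direction"], "--"
            )
            lines.append(
                f"  {e['source']} {arrow} {e['target']}: net FC {e['net_fc']:+d}"
            )
    return "\n".join(lines) + "\n"
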