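"""End-to-end orchestration: simulate -> QC -> preprocess -> ICA ->
connectivity -> classification -> family comparison.

A :class:`RunConfig` gathers every tunable of every stage; one global
seed fans out to per-stage seeds, so two runs with an identical config
produce bit-identical reports. When an output directory is given, the
expensive mid-pipeline products (seed and network time courses) are
cached keyed by a content hash of the configuration, and a rerun with
unchanged config skips straight to the cheap tail of the pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassificationSummary, OutcomeVector, loocv
from .compare import compare_all_families, comparison_report
from .connectivity import (
    FeatureMatrix,
    all_rois_all_rois,
    all_rois_nws,
    build_feature_matrix,
    nws_nws,
    separate_roi_nws,
)
from .ica import ComponentSet, IcaConfig, TemplateSet, back_reconstruct, concat_reduce, icasso_stability, match_templates
from .preprocess import (
    MotionTrace,
    VolumeSeries,
    bandpass,
    discard_initial,
    qc_motion,
    regress_nuisance,
    svd_timecourse,
)
from .rois import SYSTEMS
from .simulate import GroundTruth, SimConfig, generate_cohort
from .svm import SvmConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every tunable of the pipeline, serializable to one JSON file."""

    sim: SimConfig = field(default_factory=SimConfig)
    ica: IcaConfig = field(default_factory=IcaConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    n_discard: int = 3
    band_hz: tuple[float, float] = (0.009, 0.08)
    filter_order: int = 4
    qc_cumulative_mm: float = 3.0
    qc_p2p_translation_mm: float = 0.15
    qc_p2p_rotation_deg: float = 0.1
    bandpass_before_regression: bool = True
    clean_network_tcs: bool = False
    template_match_method: str = "regression"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["roi_specs"] = [dataclasses.asdict(s) for s in self.sim.roi_specs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .rois import RoiSpec

        d = dict(d)
        sim = dict(d.pop("sim", {}))
        if "roi_specs" in sim:
            sim["roi_specs"] = [
                RoiSpec(**{**s, "center_mm": tuple(s["center_mm"])})
                for s in sim["roi_specs"]
            ]
        for key in ("grid_dims", "grid_origin_mm", "band_hz"):
            if key in sim:
                sim[key] = tuple(sim[key])
        ica = IcaConfig(**d.pop("ica", {}))
        svm = SvmConfig(**d.pop("svm", {}))
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        return cls(sim=SimConfig(**sim), ica=ica, svm=svm, **d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json_file(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-family classification summaries plus the pairwise comparisons."""

    family_summaries: dict[str, dict]
    comparisons: list[dict]
    qc: list[dict]
    template_assignment: list[dict]
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("sim", "ica", "svm")
    return {
        nm: int(child.generate_state(1)[0] % (2**31))
        for nm, child in zip(names, ss.spawn(len(names)))
    }


class PipelineRun:
    """Stateful staged execution; every stage stores its products.

    Stages run in order via :meth:`run_to`; each is idempotent within one
    process and, for the expensive middle of the pipeline, cached on disk
    when ``out_dir`` is set.
    """

    STAGES = ("simulate", "qc", "preprocess", "ica", "connect", "classify", "compare")

    def __init__(self, config: RunConfig, out_dir: str | Path | None = None):
        self.config = config
        seeds = _stage_seeds(config.seed)
        self.config = replace(
            config,
            sim=replace(config.sim, seed=seeds["sim"]),
            ica=replace(config.ica, seed=seeds["ica"]),
            svm=replace(config.svm, seed=seeds["svm"]),
        )
        self.out_dir = Path(out_dir) if out_dir else None
        self.done: set[str] = set()
        # stage products
        self.series: list[VolumeSeries] = []
        self.motions: list[MotionTrace] = []
        self.truth: GroundTruth | None = None
        self.qc_reports: list[dict] = []
        self.kept: list[int] = []
        self.roi_tcs: list[pd.DataFrame] = []
        self.nw_tcs: list[pd.DataFrame] = []
        self.group_components: ComponentSet | None = None
        self.assignment: list[dict] = []
        self.features: dict[str, FeatureMatrix] = {}
        self.outcomes: dict[str, OutcomeVector] = {}
        self.summaries: dict[str, ClassificationSummary] = {}
        self.comparisons: pd.DataFrame | None = None
        self.report: RunReport | None = None

    # -- caching -----------------------------------------------------------
    def _cache_path(self) -> Path | None:
        if self.out_dir is None:
            return None
        return self.out_dir / "cache" / f"timecourses-{self.config.content_hash()}.npz"

    def _try_load_cache(self) -> bool:
        p = self._cache_path()
        if p is None or not p.exists():
            return False
        with np.load(p, allow_pickle=False) as z:
            n = int(z["n_subjects"])
            roi_cols = list(z["roi_columns"])
            nw_cols = list(z["nw_columns"])
            self.roi_tcs = [pd.DataFrame(z[f"roi_{i}"], columns=roi_cols) for i in range(n)]
            self.nw_tcs = [pd.DataFrame(z[f"nw_{i}"], columns=nw_cols) for i in range(n)]
            self._subject_ids = list(z["subject_ids"])
            self._group_labels = list(z["group_labels"])
            self.qc_reports = json.loads(str(z["qc_json"]))
            self.assignment = json.loads(str(z["assignment_json"]))
        logger.info("loaded cached time courses from %s", p)
        self.done.update({"simulate", "qc", "preprocess", "ica"})
        return True

    def _save_cache(self) -> None:
        p = self._cache_path()
        if p is None:
            return
        p.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "n_subjects": len(self.roi_tcs),
            "roi_columns": np.array(self.roi_tcs[0].columns, dtype=str),
            "nw_columns": np.array(self.nw_tcs[0].columns, dtype=str),
            "subject_ids": np.array(self._subject_ids, dtype=str),
            "group_labels": np.array(self._group_labels, dtype=str),
            "qc_json": np.array(json.dumps(self.qc_reports)),
            "assignment_json": np.array(json.dumps(self.assignment)),
        }
        for i, (r, nw) in enumerate(zip(self.roi_tcs, self.nw_tcs)):
            payload[f"roi_{i}"] = r.to_numpy(float)
            payload[f"nw_{i}"] = nw.to_numpy(float)
        np.savez(p, **payload)

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> None:
        self.series, self.motions, self.truth = generate_cohort(self.config.sim)

    def stage_qc(self) -> None:
        cfg = self.config
        kept, reports = [], []
        trimmed_series, trimmed_motion = [], []
        for i, (s, m) in enumerate(zip(self.series, self.motions)):
            s2 = discard_initial(s, cfg.n_discard)
            m2 = m.trim(cfg.n_discard)
            rep = qc_motion(
                m2,
                s2,
                cumulative_mm=cfg.qc_cumulative_mm,
                p2p_translation_mm=cfg.qc_p2p_translation_mm,
                p2p_rotation_deg=cfg.qc_p2p_rotation_deg,
            )
            reports.append({**rep.__dict__, "subject_id": s.subject_id})
            if rep.excluded:
                logger.warning("excluding %s: %s", s.subject_id, "; ".join(rep.reasons))
                continue
            kept.append(i)
            trimmed_series.append(s2)
            trimmed_motion.append(m2)
        if len(kept) < 4:
            raise RuntimeError("fewer than 4 subjects survive quality control")
        self.qc_reports = reports
        self.kept = kept
        self.series = trimmed_series
        self.motions = trimmed_motion
        self._subject_ids = [s.subject_id for s in trimmed_series]
        self._group_labels = [self.truth.group_labels[i] for i in kept]

    def _nuisance(self, series: VolumeSeries, motion: MotionTrace) -> np.ndarray:
        t = self.truth
        sig = np.vstack(
            [
                series.data[t.gm_mask].mean(axis=0),
                series.data[t.wm_mask].mean(axis=0),
                series.data[t.csf_mask].mean(axis=0),
                motion.translations_mm,
                motion.rotations_deg,
            ]
        )
        if self.config.bandpass_before_regression:
            sig = bandpass(
                sig, *self.config.band_hz, series.tr_seconds, self.config.filter_order
            )
        return sig.T  # (T, 9)

    def stage_preprocess(self) -> None:
        cfg = self.config
        roi_masks = self.truth.roi_masks
        tcs = []
        for s, m in zip(self.series, self.motions):
            reg = self._nuisance(s, m)
            cols = {}
            for mask in roi_masks:
                sub = s.data[mask.indices].astype(float)
                if cfg.bandpass_before_regression:
                    sub = bandpass(sub, *cfg.band_hz, s.tr_seconds, cfg.filter_order)
                rep = svd_timecourse(sub, name=mask.name)
                clean = regress_nuisance(rep.values, reg)
                if not cfg.bandpass_before_regression:
                    clean = bandpass(clean, *cfg.band_hz, s.tr_seconds, cfg.filter_order)
                cols[mask.name] = clean
            tcs.append(pd.DataFrame(cols))
        self.roi_tcs = tcs

    def stage_ica(self) -> None:
        cfg = self.config
        data = [s.data for s in self.series]
        group_mat, _ops = concat_reduce(data, cfg.ica)
        self.group_components = icasso_stability(group_mat, cfg.ica)
        templates = TemplateSet(
            maps=self.truth.latent_network_maps,
            names=[f"NW{k + 1:02d}" for k in range(self.truth.latent_network_maps.shape[0])],
        )
        self.assignment = match_templates(
            self.group_components, templates, method=cfg.template_match_method
        )
        sel = [a["component"] for a in self.assignment]
        signs = np.sign([a["goodness"] or 1.0 for a in self.assignment])
        maps = self.group_components.spatial_maps[sel] * signs[:, None]
        selected = ComponentSet(spatial_maps=maps, provenance="group-selected")
        nw_names = [a["template"] for a in self.assignment]
        out = []
        for s, m in zip(self.series, self.motions):
            subj = back_reconstruct(selected, s.data)
            tc = subj.timecourses
            if cfg.clean_network_tcs:
                reg = self._nuisance(s, m)
                tc = bandpass(tc.T, *cfg.band_hz, s.tr_seconds, cfg.filter_order)
                tc = regress_nuisance(tc, reg).T
            out.append(pd.DataFrame(tc, columns=nw_names))
        self.nw_tcs = out

    def stage_connect(self) -> None:
        roi_names = list(self.roi_tcs[0].columns)
        nw_names = list(self.nw_tcs[0].columns)
        systems = [s for s in SYSTEMS if any(n.startswith(s) for n in roi_names)]
        fams = [
            all_rois_nws(roi_names, nw_names),
            nws_nws(nw_names),
            all_rois_all_rois(roi_names),
        ]
        for system in systems:
            names = [n for n in roi_names if n.startswith(system)]
            fams.append(separate_roi_nws(system, names, nw_names))
        self.features = {
            f.name: build_feature_matrix(
                self.roi_tcs, self.nw_tcs, f, self._subject_ids, self._group_labels
            )
            for f in fams
        }

    def stage_classify(self) -> None:
        for name, fm in self.features.items():
            out, summ = loocv(fm, self.config.svm)
            self.outcomes[name] = out
            self.summaries[name] = summ

    def stage_compare(self) -> None:
        self.comparisons = compare_all_families(self.outcomes)

    # -- driver ------------------------------------------------------------
    def run_to(self, last_stage: str = "compare") -> RunReport:
        if last_stage not in self.STAGES:
            raise ValueError(f"unknown stage {last_stage!r}")
        upto = self.STAGES.index(last_stage)
        if "ica" not in self.done and upto >= self.STAGES.index("ica"):
            self._try_load_cache()
        for stage in self.STAGES[: upto + 1]:
            if stage in self.done:
                continue
            t0 = time.perf_counter()
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            self.done.add(stage)
            logger.info("stage %-10s %6.2f s", stage, time.perf_counter() - t0)
            if stage == "ica":
                self._save_cache()
                self.series = []  # voxel data no longer needed
        if upto == len(self.STAGES) - 1:
            self.report = self._build_report()
            if self.out_dir is not None:
                self._write_artifacts()
        return self.report

    def _build_report(self) -> RunReport:
        return RunReport(
            family_summaries={k: v.as_dict() for k, v in self.summaries.items()},
            comparisons=self.comparisons.to_dict(orient="records"),
            qc=self.qc_reports,
            template_assignment=self.assignment,
            provenance={
                "config_hash": self.config.content_hash(),
                "seed": self.config.seed,
                "version": __version__,
                "n_subjects_classified": len(self._subject_ids),
            },
        )

    def _write_artifacts(self) -> None:
        out = self.out_dir
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.report.to_json())
        (out / "config.json").write_text(self.config.to_json())
        for name, fm in self.features.items():
            fm.to_tsv(out / f"features_{_slug(name)}.tsv")
        for name, ov in self.outcomes.items():
            ov.to_frame().to_csv(out / f"outcomes_{_slug(name)}.csv", index=False)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        for rep in self.qc_reports:
            (qc_dir / f"{rep['subject_id']}.json").write_text(
                json.dumps(rep, indent=2, sort_keys=True)
            )
        tc_dir = out / "timecourses"
        tc_dir.mkdir(exist_ok=True)
        for sid, roi_df, nw_df in zip(self._subject_ids, self.roi_tcs, self.nw_tcs):
            roi_df.to_csv(tc_dir / f"{sid}_roi.tsv", sep="\t", index=False, float_format="%.8g")
            nw_df.to_csv(tc_dir / f"{sid}_networks.tsv", sep="\t", index=False, float_format="%.8g")
        global_fams = [f for f in ("allROIs-NWs", "NWs-NWs", "allROIs-allROIs") if f in self.outcomes]
        system_fams = [f"{s}-NWs" for s in SYSTEMS if f"{s}-NWs" in self.outcomes]
        md = [
            "# Classification consistency report",
            "",
            "## Per-family classification (accuracy as pattern consistency)",
            "",
            "| family | accuracy | sensitivity | specificity | n |",
            "|---|---|---|---|---|",
        ]
        for name, s in self.summaries.items():
            md.append(
                f"| {name} | {100 * s.accuracy:.1f}% | {s.sensitivity:.2f} | {s.specificity:.2f} | {s.n} |"
            )
        md += ["", "## Pairwise exact binomial p-values (global families)", ""]
        md.append(comparison_report(self.comparisons, global_fams))
        md += ["", "## Pairwise exact binomial p-values (single systems)", ""]
        md.append(comparison_report(self.comparisons, system_fams))
        (out / "report.md").write_text("\n".join(md) + "\n")


def _slug(name: str) -> str:
    return name.replace("-", "_").replace(" ", "_")


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute all stages in order and return the report."""
    return PipelineRun(config, out_dir=out_dir).run_to("compare")
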