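"""Study orchestration: intra-site age-group cross-testing, inter-site
domain-shift experiments with MoM harmonization and fine-tuning, gold-
standard split-half consistency, and report serialization.

Every experiment is driven by one :class:`ExperimentConfig` and a master
seed; all cohorts, model initializations, subject orderings and noise draws
derive from it, so a run is reproducible end to end.  Cohort sizes default
to a desk scale that preserves the study's split ratios: 20 subjects per
site split 14/3/3 (mirroring 70/15/15) and 12 per age group split 8/2/2
(mirroring 40/10/10).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import harmonize_mom as hm
from .fod_estimator import EstimatorConfig, TrainedEstimator, finetune, predict, select_six_directions, train
from .fod_reference import estimate_response, split_half_consistency
from .metrics_eval import MetricsReport, evaluate
from .sh_core import PeakParams
from .synthetic_cohort import (
    DEFAULT_AGE_MODEL,
    AgeModel,
    GeometrySpec,
    SiteProfile,
    SubjectPhantom,
    bcp_like_scheme,
    dhcp_like_scheme,
    generate_cohort,
    make_site_profile,
)

__all__ = [
    "SiteSettings",
    "ExperimentConfig",
    "StudyReport",
    "run_intra_site",
    "run_inter_site",
    "run_gs_consistency",
    "write_report",
    "load_report",
    "aggregate_reports",
]


@dataclass(frozen=True)
class SiteSettings:
    """One acquisition site of the study: scheme family, signal shifts,
    noise level, and the age structure of its cohort (postnatal months)."""

    name: str
    scheme_kind: str  # "dhcp" | "bcp"
    gain_amplitude: float = 0.0
    offset_frac: float = 0.0
    rician_sigma: float = 0.02
    age_range: tuple[float, float] = (-2.5, 1.0)
    age_young: tuple[float, float] = (-3.1, -1.2)
    age_old: tuple[float, float] = (0.0, 1.0)

    def scheme(self):
        if self.scheme_kind == "dhcp":
            return dhcp_like_scheme()
        if self.scheme_kind == "bcp":
            return bcp_like_scheme()
        raise ValueError(f"unknown scheme kind {self.scheme_kind!r}")


#: newborn-like site: no site shift (the reference), dHCP-like scheme, ages
#: spanning late preterm to term-equivalent (post-menstrual 29-44 weeks).
DEFAULT_SITE_A = SiteSettings(name="dhcp", scheme_kind="dhcp")

#: baby-like site: smooth gain and additive offset plus a higher noise
#: floor emulate the scanner/protocol change; ages 1.5-60 months; the age
#: groups mirror the study's young/old windows.
DEFAULT_SITE_B = SiteSettings(
    name="bcp",
    scheme_kind="bcp",
    gain_amplitude=0.1,
    offset_frac=0.6,
    rician_sigma=0.03,
    age_range=(1.5, 60.0),
    age_young=(0.5, 11.0),
    age_old=(20.0, 36.0),
)


def _default_estimator() -> EstimatorConfig:
    return EstimatorConfig(hidden_channels=(128, 128), max_voxels_per_subject=1500)


@dataclass
class ExperimentConfig:
    """Full study configuration; defaults are the desk-scale conditions."""

    site_a: SiteSettings = DEFAULT_SITE_A
    site_b: SiteSettings = DEFAULT_SITE_B
    age_model_a: AgeModel = DEFAULT_AGE_MODEL
    age_model_b: AgeModel = DEFAULT_AGE_MODEL
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    geometry: GeometrySpec = field(default_factory=lambda: GeometrySpec(margin=4))
    n_cohort: int = 20
    split: tuple[int, int, int] = (14, 3, 3)  # train/val/test, ratio 70/15/15
    n_age_group: int = 12
    age_split: tuple[int, int, int] = (8, 2, 2)  # ratio 40/10/10
    n_target: tuple[int, ...] = (1, 2, 5, 10)
    n_ft_intra: int = 5  # intra-site fine-tuning subjects
    estimator: EstimatorConfig = field(default_factory=_default_estimator)
    smoothing_sigma: float = 1.0
    var_floor: float = 1e-6
    peak_params: PeakParams = field(default_factory=PeakParams)
    seed: int = 0

    def __post_init__(self):
        if sum(self.split) != self.n_cohort:
            raise ValueError("split must sum to n_cohort")
        if sum(self.age_split) != self.n_age_group:
            raise ValueError("age_split must sum to n_age_group")
        if max(self.n_target) > self.split[0]:
            raise ValueError("n_target cannot exceed the training split")

    def config_hash(self) -> str:
        blob = json.dumps(_to_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def site_shift_only(cls, seed: int = 0, **overrides) -> "ExperimentConfig":
        """Study conditions isolating the scanner/protocol shift: both
        cohorts share the age distribution, so the only cross-site
        differences are the scheme, the smooth gain/offset fields and the
        Rician noise level.  The default configuration instead emulates the
        full two-cohort setting where age structure differs as well."""
        site_b = replace(
            DEFAULT_SITE_B,
            age_range=DEFAULT_SITE_A.age_range,
            age_young=DEFAULT_SITE_A.age_young,
            age_old=DEFAULT_SITE_A.age_old,
        )
        return cls(site_b=site_b, seed=seed, **overrides)

    def site_profile(self, site: SiteSettings) -> SiteProfile:
        return make_site_profile(
            site.name,
            site.scheme(),
            self.grid_shape,
            gain_amplitude=site.gain_amplitude,
            offset_frac=site.offset_frac,
            rician_sigma=site.rician_sigma,
        )

    def age_model(self, site: SiteSettings) -> AgeModel:
        return self.age_model_a if site is self.site_a or site.name == self.site_a.name else self.age_model_b

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kw = dict(raw)
        for key in ("site_a", "site_b"):
            if key in kw and isinstance(kw[key], dict):
                d = dict(kw[key])
                for t in ("age_range", "age_young", "age_old"):
                    if t in d:
                        d[t] = tuple(d[t])
                kw[key] = SiteSettings(**d)
        for key in ("age_model_a", "age_model_b"):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = AgeModel(**kw[key])
        if "geometry" in kw and isinstance(kw["geometry"], dict):
            g = dict(kw["geometry"])
            if "shares" in g:
                g["shares"] = tuple(g["shares"])
            if "crossing_angle_range" in g:
                g["crossing_angle_range"] = tuple(g["crossing_angle_range"])
            kw["geometry"] = GeometrySpec(**g)
        if "estimator" in kw and isinstance(kw["estimator"], dict):
            e = dict(kw["estimator"])
            if "hidden_channels" in e:
                e["hidden_channels"] = tuple(e["hidden_channels"])
            kw["estimator"] = EstimatorConfig(**e)
        if "peak_params" in kw and isinstance(kw["peak_params"], dict):
            kw["peak_params"] = PeakParams(**kw["peak_params"])
        for t in ("grid_shape", "split", "age_split", "n_target"):
            if t in kw:
                kw[t] = tuple(kw[t])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_jsonable(asdict(self))))


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class StudyReport:
    """Per-arm metric reports plus full provenance."""

    arms: dict[str, MetricsReport]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "arms": {k: v.to_dict() for k, v in self.arms.items()},
            "provenance": _to_jsonable(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyReport":
        return cls(
            arms={k: MetricsReport.from_dict(v) for k, v in d["arms"].items()},
            provenance=d["provenance"],
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for arm, rep in self.arms.items():
            row = {"arm": arm}
            for k in (1, 2, 3):
                row[f"ar_{k}f"] = rep.ar_by_k.get(k)
                row[f"ae_{k}f"] = rep.ae_by_k.get(k)
                row[f"n_vox_{k}f"] = rep.n_voxels_by_k.get(k)
            row["afd_error"] = rep.afd_error
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# helpers


def _derive_seed(master: int, tag: int) -> int:
    return int(np.random.SeedSequence((master, tag)).generate_state(1)[0] % (2**31 - 1))


def aggregate_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Unweighted mean over subjects of every populated metric; voxel and
    pair counts are summed.  A stratum missing in every subject stays missing."""

    def mean_or_none(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    ar = {k: mean_or_none([r.ar_by_k.get(k) for r in reports]) for k in (1, 2, 3)}
    ae = {k: mean_or_none([r.ae_by_k.get(k) for r in reports]) for k in (1, 2, 3)}
    return MetricsReport(
        ar_by_k=ar,
        ae_by_k=ae,
        afd_error=float(np.mean([r.afd_error for r in reports])),
        n_voxels_by_k={k: int(sum(r.n_voxels_by_k.get(k, 0) for r in reports)) for k in (1, 2, 3)},
        n_matched_pairs_by_k={
            k: int(sum(r.n_matched_pairs_by_k.get(k, 0) for r in reports)) for k in (1, 2, 3)
        },
        extras={"n_subjects": len(reports)},
    )


def _evaluate_arm(
    model: TrainedEstimator,
    subjects: list[SubjectPhantom],
    six_indices,
    peak_params: PeakParams,
    dwis: list[np.ndarray] | None = None,
) -> MetricsReport:
    reports = []
    for i, s in enumerate(subjects):
        dwi = s.dwi if dwis is None else dwis[i]
        pred = predict(model, dwi=dwi, scheme=s.scheme, six_indices=six_indices)
        reports.append(evaluate(s.gt_fod, pred, s.wm_mask, peak_params, include_three_fiber=False))
    return aggregate_reports(reports)


def _params_digest(model: TrainedEstimator) -> str:
    h = hashlib.sha256()
    for p in model.params:
        h.update(p["w"].tobytes())
        h.update(p["b"].tobytes())
    return h.hexdigest()


def _array_digest(arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def _assert_disjoint(**groups):
    ids = {k: {s.subject_id for s in v} for k, v in groups.items()}
    keys = list(ids)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            common = ids[ka] & ids[kb]
            if common:
                raise RuntimeError(f"data leakage: {ka} and {kb} share subjects {sorted(common)}")


def _harmonize_subject_dwi(subject: SubjectPhantom, six_indices, mapping: hm.HarmonizationField) -> np.ndarray:
    """Apply the voxelwise (alpha, beta) to the six selected directions and,
    with the same pair, to the b=0 volumes used for normalization."""
    dwi = np.array(subject.dwi, dtype=float)
    six = np.asarray(list(six_indices))
    b0_idx = np.nonzero(subject.scheme.b0_mask)[0]
    dwi[..., six] = hm.apply_mapping(dwi[..., six], mapping)
    dwi[..., b0_idx] = np.maximum(
        mapping.alpha[..., None] * dwi[..., b0_idx] + mapping.beta[..., None], 0.0
    )
    return dwi


# ---------------------------------------------------------------------------
# study designs


def _train_model(config: ExperimentConfig, train_subjects, val_subjects, six, seed_tag: int) -> TrainedEstimator:
    est = replace(config.estimator, seed=_derive_seed(config.seed, seed_tag))
    return train(est, train_subjects, val_subjects, six_indices=six)


def _site_cohort(config: ExperimentConfig, site: SiteSettings, age_range, seed_tag: int, n: int):
    profile = config.site_profile(site)
    return generate_cohort(
        n,
        age_range,
        profile,
        age_model=config.age_model(site),
        geometry_spec=config.geometry,
        seed=_derive_seed(config.seed, seed_tag),
        grid_shape=config.grid_shape,
    )


def run_intra_site(config: ExperimentConfig, site_key: str = "a") -> StudyReport:
    """Age-specific training and cross-testing within one site.

    Trains DL_young and DL_old on that site's young/old age groups and
    reports the arm set {y->y, y->o, o->y, o->o, y->o^FT, o->y^FT}; the
    fine-tuned arms adapt the source-age model with ``n_ft_intra`` subjects
    from the target age group's training split.
    """
    site = config.site_a if site_key == "a" else config.site_b
    n_tr, n_va, n_te = config.age_split
    young = _site_cohort(config, site, site.age_young, 10, config.n_age_group)
    old = _site_cohort(config, site, site.age_old, 11, config.n_age_group)
    six = select_six_directions(site.scheme())
    groups = {}
    for tag, cohort in (("y", young), ("o", old)):
        groups[tag] = {
            "train": cohort[:n_tr],
            "val": cohort[n_tr : n_tr + n_va],
            "test": cohort[n_tr + n_va :],
        }
    models = {
        "y": _train_model(config, groups["y"]["train"], groups["y"]["val"], six, 20),
        "o": _train_model(config, groups["o"]["train"], groups["o"]["val"], six, 21),
    }
    arms = {}
    for src in ("y", "o"):
        for tgt in ("y", "o"):
            _assert_disjoint(
                train=groups[src]["train"] + groups[src]["val"], test=groups[tgt]["test"]
            )
            arms[f"{src}->{tgt}"] = _evaluate_arm(
                models[src], groups[tgt]["test"], six, config.peak_params
            )
    for src, tgt in (("y", "o"), ("o", "y")):
        ft_subjects = groups[tgt]["train"][: config.n_ft_intra]
        _assert_disjoint(finetune=ft_subjects, test=groups[tgt]["test"])
        ft = finetune(models[src], ft_subjects, six_indices=six)
        arms[f"{src}->{tgt}^FT"] = _evaluate_arm(ft, groups[tgt]["test"], six, config.peak_params)
    prov = {
        "design": "intra_site",
        "site": site.name,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "subjects": {
            f"{g}_{split}": [s.subject_id for s in groups[g][split]]
            for g in ("y", "o")
            for split in ("train", "val", "test")
        },
    }
    return StudyReport(arms=arms, provenance=prov)


def run_inter_site(config: ExperimentConfig, directions: tuple[str, ...] = ("a_to_b", "b_to_a")) -> StudyReport:
    """Cross-site domain-shift study.

    For each direction source->target: the target-trained baseline on its
    own test set (self, the upper bound), raw cross-testing, MoM(n) —
    harmonize the target test data toward the source using moment maps from
    n target training subjects, evaluated with the unmodified source model
    — FT(n) — fine-tune the source model on the same n subjects, evaluated
    on unmodified target data — and a from-scratch model trained only on
    the 10 target subjects.  Target subject subsets are nested across n.
    """
    sites = {"a": config.site_a, "b": config.site_b}
    cohorts = {
        "a": _site_cohort(config, config.site_a, config.site_a.age_range, 30, config.n_cohort),
        "b": _site_cohort(config, config.site_b, config.site_b.age_range, 31, config.n_cohort),
    }
    n_tr, n_va, n_te = config.split
    splits = {
        k: {"train": c[:n_tr], "val": c[n_tr : n_tr + n_va], "test": c[n_tr + n_va :]}
        for k, c in cohorts.items()
    }
    six = {k: select_six_directions(sites[k].scheme()) for k in sites}
    models = {
        "a": _train_model(config, splits["a"]["train"], splits["a"]["val"], six["a"], 40),
        "b": _train_model(config, splits["b"]["train"], splits["b"]["val"], six["b"], 41),
    }
    arms = {}
    prov_subjects = {
        f"{k}_{sp}": [s.subject_id for s in splits[k][sp]] for k in splits for sp in splits[k]
    }
    prov_n_used = {}
    for direction in directions:
        src, tgt = direction.split("_to_")
        test = splits[tgt]["test"]
        _assert_disjoint(
            source_train=splits[src]["train"] + splits[src]["val"],
            target_train=splits[tgt]["train"] + splits[tgt]["val"],
            test=test,
        )
        arms[f"self_{tgt}"] = _evaluate_arm(models[tgt], test, six[tgt], config.peak_params)
        arms[f"cross_{direction}"] = _evaluate_arm(models[src], test, six[tgt], config.peak_params)
        # nested target-subject subsets, order fixed by the master seed
        order = np.random.default_rng(_derive_seed(config.seed, 50)).permutation(n_tr)
        target_pool = [splits[tgt]["train"][i] for i in order]
        ref_maps = hm.compute_moment_maps(splits[src]["train"], six[src], config.smoothing_sigma)
        test_digest = _array_digest([s.dwi for s in test])
        for n in config.n_target:
            subset = target_pool[:n]
            prov_n_used[f"{direction}_n{n}"] = [s.subject_id for s in subset]
            if len(subset) < n:
                raise RuntimeError(f"requested {n} target subjects, only {len(subset)} available")
            _assert_disjoint(target_subset=subset, test=test)
            # --- MoM arm: signals move, the model does not
            model_digest = _params_digest(models[src])
            src_maps = hm.compute_moment_maps(subset, six[tgt], config.smoothing_sigma)
            mapping = hm.derive_mapping(src_maps, ref_maps, var_floor=config.var_floor)
            harmonized = [_harmonize_subject_dwi(s, six[tgt], mapping) for s in test]
            arms[f"mom_{direction}_n{n}"] = _evaluate_arm(
                models[src], test, six[tgt], config.peak_params, dwis=harmonized
            )
            assert _params_digest(models[src]) == model_digest, "MoM arm modified the model"
            # --- FT arm: the model moves, test signals do not
            ft = finetune(models[src], subset, six_indices=six[tgt])
            arms[f"ft_{direction}_n{n}"] = _evaluate_arm(ft, test, six[tgt], config.peak_params)
            assert _array_digest([s.dwi for s in test]) == test_digest, "FT arm modified test data"
        # --- scratch ablation on the widest target subset
        n_scr = max(config.n_target)
        scr_pool = target_pool[:n_scr]
        n_scr_val = max(1, n_scr // 5)
        scratch_tag = 61 if direction == "a_to_b" else 62
        scratch = _train_model(
            config, scr_pool[:-n_scr_val], scr_pool[-n_scr_val:], six[tgt], scratch_tag
        )
        arms[f"scratch_{tgt}_n{n_scr}"] = _evaluate_arm(scratch, test, six[tgt], config.peak_params)
    prov = {
        "design": "inter_site",
        "directions": list(directions),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "subjects": prov_subjects,
        "target_subsets": prov_n_used,
    }
    return StudyReport(arms=arms, provenance=prov)


def run_gs_consistency(config: ExperimentConfig, site_key: str = "a") -> MetricsReport:
    """Gold-standard split-half CSD consistency on a site's test subjects,
    aggregated as an unweighted mean across subjects."""
    site = config.site_a if site_key == "a" else config.site_b
    cohort = _site_cohort(config, site, site.age_range, 30 if site_key == "a" else 31, config.n_cohort)
    n_tr, n_va, _ = config.split
    test = cohort[n_tr + n_va :]
    reports = []
    for s in test:
        sf_mask = s.fiber_config.counts == 1
        response = estimate_response(s.dwi, s.scheme, sf_mask)
        reports.append(
            split_half_consistency(
                s.dwi, s.scheme, response, s.wm_mask, peak_params=config.peak_params
            )
        )
    agg = aggregate_reports(reports)
    agg.extras["design"] = "gs_consistency"
    agg.extras["site"] = site.name
    return agg


def write_report(report: StudyReport, out_dir, formats=("csv", "json"), plots: bool = False) -> list[Path]:
    """Serialize a study report; CSV rows mirror the AR/AE-per-stratum plus
    AFD-error table layout.  Deterministic for fixed inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if "csv" in formats:
        p = out / "report.csv"
        report.to_dataframe().to_csv(p, index=False, float_format="%.6g")
        written.append(p)
    if "json" in formats:
        p = out / "report.json"
        p.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        written.append(p)
    if plots:
        written.append(_plot_single_fiber_ar(report, out / "ar_single_fiber.png"))
    return written


def load_report(path) -> StudyReport:
    return StudyReport.from_dict(json.loads(Path(path).read_text()))


def _plot_single_fiber_ar(report: StudyReport, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arms = [(k, v.ar_by_k.get(1)) for k, v in report.arms.items() if v.ar_by_k.get(1) is not None]
    fig, ax = plt.subplots(figsize=(1.2 + 0.6 * len(arms), 4))
    ax.bar([a for a, _ in arms], [v for _, v in arms], color="steelblue")
    ax.set_ylabel("single-fiber agreement rate (%)")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
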