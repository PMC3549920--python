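"""Study orchestration: leave-one-subject-out cross-validation with in-fold
feature selection, error accounting, stability aggregation, distance-profile
group comparison, and the end-to-end synthetic study.

Feature ranking is recomputed inside every training fold (t-test p-values on
training rows only); selecting on the full table would leak the held-out
subject and produce overly optimistic error estimates.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classifiers, glm_activation, group_stats, network_features
from .group_stats import FeatureTable
from .synthetic_cohort import SubjectRecord, default_config, generate_cohort

__all__ = [
    "CvFold",
    "EvalResult",
    "make_losocv_folds",
    "run_cv_experiment",
    "baseline_accuracy",
    "distance_group_comparison",
    "build_feature_tables",
    "run_full_study",
]

POSITIVE_CLASS = "patient"


@dataclass(frozen=True)
class CvFold:
    held_out_subject: str
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class EvalResult:
    """Cross-validated rates per k: error, false-positive and false-negative
    fractions with "patient" as the positive class."""

    kind: str
    classifier: str
    k_grid: list[int]
    error: dict[int, float]
    false_positive: dict[int, float]
    false_negative: dict[int, float]
    fold_predictions: dict[int, list]  # k -> [(sample idx, true, predicted)]
    fold_topk: dict[int, list]  # k -> list of per-fold selected id arrays

    def stability(self, k: int) -> float:
        return group_stats.stability(self.fold_topk[k], k)


def make_losocv_folds(samples: list[tuple[str, str, str]]) -> list[CvFold]:
    """One fold per subject; the fold's test set is exactly that subject's
    two run-samples.  Samples are (subject_id, run_id, label) triples."""
    subjects: dict[str, list[int]] = {}
    groups: dict[str, str] = {}
    for i, (sid, _run, label) in enumerate(samples):
        subjects.setdefault(sid, []).append(i)
        if sid in groups and groups[sid] != label:
            raise ValueError(f"subject {sid!r} appears with conflicting labels")
        groups[sid] = label
    folds = []
    all_idx = np.arange(len(samples))
    for sid in sorted(subjects):
        idx = subjects[sid]
        if len(idx) != 2:
            raise ValueError(f"subject {sid!r} has {len(idx)} samples, expected 2")
        test = np.array(idx)
        train = np.setdiff1d(all_idx, test)
        folds.append(CvFold(held_out_subject=sid, train_idx=train, test_idx=test))
    return folds


def baseline_accuracy(labels) -> float:
    """Majority-class accuracy."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label list")
    _, counts = np.unique(labels, return_counts=True)
    return float(counts.max() / labels.size)


def run_cv_experiment(
    table: FeatureTable,
    kind: str,
    k_grid: list[int],
    params: dict | None = None,
) -> EvalResult:
    """LOSOCV with per-fold top-k feature selection.

    For each fold and each k: rank features by training-rows-only t-test
    p-values, restrict both splits to those feature ids, fit the classifier,
    predict the two held-out samples.  Rates are pooled over folds.
    """
    if any(k < 1 or k > table.n_features for k in k_grid):
        raise ValueError("k_grid values must lie in [1, n_features]")
    samples = [
        (sid, str(i), lab)
        for i, (sid, lab) in enumerate(zip(table.subject_ids, table.labels))
    ]
    folds = make_losocv_folds(samples)

    predictions: dict[int, list] = {k: [] for k in k_grid}
    topk_sets: dict[int, list] = {k: [] for k in k_grid}
    col_of = {fid: j for j, fid in enumerate(table.feature_ids.tolist())}

    for fold in folds:
        assert not np.intersect1d(fold.train_idx, fold.test_idx).size
        train = table.subset(rows=fold.train_idx)
        stats_res = group_stats.two_sample_ttest(train)
        for k in k_grid:
            ids = group_stats.rank_topk(stats_res.pvalues, k, train.feature_ids)
            cols = np.array([col_of[f] for f in ids.tolist()])
            try:
                model = classifiers.fit_classifier(
                    kind, (table.values[fold.train_idx][:, cols],
                           table.labels[fold.train_idx]), params
                )
                pred = classifiers.predict(model, table.values[fold.test_idx][:, cols])
            except Exception as exc:  # noqa: BLE001 - annotate fold context
                raise RuntimeError(
                    f"classifier {kind!r} failed in fold "
                    f"{fold.held_out_subject!r} at k={k}: {exc}"
                ) from exc
            for i, p in zip(fold.test_idx, pred):
                predictions[k].append((int(i), str(table.labels[i]), str(p)))
            topk_sets[k].append(ids)

    error, fp, fn = {}, {}, {}
    for k in k_grid:
        preds = predictions[k]
        wrong = sum(t != p for _, t, p in preds)
        pos = [(t, p) for _, t, p in preds if t == POSITIVE_CLASS]
        neg = [(t, p) for _, t, p in preds if t != POSITIVE_CLASS]
        error[k] = wrong / len(preds)
        fp[k] = sum(p == POSITIVE_CLASS for _, p in neg) / len(neg) if neg else 0.0
        fn[k] = sum(p != POSITIVE_CLASS for _, p in pos) / len(pos) if pos else 0.0
    return EvalResult(
        kind=table.kind, classifier=kind, k_grid=list(k_grid),
        error=error, false_positive=fp, false_negative=fn,
        fold_predictions=predictions, fold_topk=topk_sets,
    )


def distance_group_comparison(
    graphs: list[tuple[str, network_features.FunctionalGraph]],
    bin_width: float = 5.0,
    fit_range: tuple[float, float] = (10.0, 150.0),
    roi_pair: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Distance-resolved group contrast.

    Per group: mean +/- sd link-probability profile and its power-law fit;
    per-sample inter-hemispheric (and optionally bilateral-ROI) link
    fractions compared between groups with a two-sample t-test.
    """
    by_group: dict[str, list] = {"patient": [], "control": []}
    for label, graph in graphs:
        by_group[label].append(graph)
    if any(len(v) < 2 for v in by_group.values()):
        raise ValueError("need at least 2 graphs per group")

    report: dict = {"groups": {}}
    fractions: dict[str, list[float]] = {}
    roi_fractions: dict[str, list[float]] = {}
    for label, glist in by_group.items():
        profiles = [
            network_features.link_probability_by_distance(g, bin_width) for g in glist
        ]
        centers = profiles[0].bin_centers
        common = min(len(p.link_probability) for p in profiles)
        stack = np.stack([p.link_probability[:common] for p in profiles])
        mean_profile = stack.mean(axis=0)
        pooled = network_features.DistanceProfile(
            bin_centers=centers[:common],
            link_probability=mean_profile,
            link_probability_sd=stack.std(axis=0),
            n_pairs=profiles[0].n_pairs[:common],
        )
        try:
            a, gamma = network_features.fit_power_law(pooled, *fit_range)
        except ValueError:
            a, gamma = float("nan"), float("nan")
        fractions[label] = [
            network_features.interhemispheric_fraction(g) for g in glist
        ]
        if roi_pair is not None:
            roi_fractions[label] = [
                network_features.roi_pair_link_fraction(g, *roi_pair) for g in glist
            ]
        report["groups"][label] = {
            "bin_centers_mm": pooled.bin_centers.tolist(),
            "mean_link_probability": mean_profile.tolist(),
            "sd_link_probability": stack.std(axis=0).tolist(),
            "power_law_amplitude": a,
            "power_law_gamma": gamma,
        }

    from scipy import stats as sps

    t, p = sps.ttest_ind(fractions["control"], fractions["patient"])
    report["interhemispheric"] = {
        "mean_control": float(np.mean(fractions["control"])),
        "mean_patient": float(np.mean(fractions["patient"])),
        "t": float(t),
        "pvalue": float(p),
        "pvalue_one_sided_control_gt": float(p / 2.0) if t > 0 else 1.0 - float(p / 2.0),
    }
    if roi_pair is not None:
        t2, p2 = sps.ttest_ind(roi_fractions["control"], roi_fractions["patient"])
        report["roi_pair"] = {
            "mean_control": float(np.mean(roi_fractions["control"])),
            "mean_patient": float(np.mean(roi_fractions["patient"])),
            "t": float(t2),
            "pvalue": float(p2),
        }
    return report


# --------------------------------------------------------------------------
# end-to-end synthetic study


def build_feature_tables(
    records: list[SubjectRecord],
    contrast_ids: tuple[int, ...] = (1, 6, 8),
    threshold: float = 0.7,
    compute_heavy_maps: bool = True,
    compute_globals: bool = True,
    keep_graphs: bool = True,
    n_edge_pairs: int = 0,
    edge_seed: int = 0,
) -> dict:
    """Per-sample activation and network feature tables for a cohort.

    Returns a dict with FeatureTables keyed by kind (normalized activation
    contrasts and degree maps, raw strength/clustering/efficiency maps, and
    optionally ``n_edge_pairs`` sampled edge weights — the pair locations
    are drawn once from ``edge_seed`` and reused for every sample), plus
    per-sample graphs, global features, and motion summaries.
    """
    labels, subject_ids = [], []
    act: dict[int, list] = {cid: [] for cid in contrast_ids}
    deg: dict[str, list] = {k: [] for k in ("degree_full", "degree_long", "degree_interhemi")}
    heavy: dict[str, list] = {
        k: [] for k in ("strength", "strength_abs", "strength_pos",
                        "clustering", "local_efficiency")
    }
    graphs, globals_, motion_summary, mean_tvals = [], [], [], []
    edge_pairs = None
    edge_rows: list[np.ndarray] = []

    for rec in records:
        for run, motion, paradigm in zip(rec.runs, rec.motion, rec.paradigms):
            labels.append(rec.group)
            subject_ids.append(rec.subject_id)
            design = glm_activation.build_design_matrix(paradigm, motion)
            fit = glm_activation.fit_glm(run, design)
            for cid in contrast_ids:
                amap = glm_activation.contrast_tmap(
                    fit, design, glm_activation.contrast_vector(design, cid),
                    name=glm_activation.CONTRAST_NAMES[cid],
                )
                act[cid].append(glm_activation.normalize_map(amap).tvalues)
            mean_tvals.append(
                glm_activation.mean_abs_t(
                    glm_activation.contrast_tmap(
                        fit, design, glm_activation.contrast_vector(design, 8),
                        name="Silence",
                    )
                )
            )

            corr = network_features.pairwise_correlations(run)
            if n_edge_pairs:
                if edge_pairs is None:
                    edge_pairs = network_features.sample_edges(
                        corr.n_voxels, n_edge_pairs, edge_seed
                    )
                edge_rows.append(corr.full[edge_pairs[:, 0], edge_pairs[:, 1]])
            graph = network_features.build_graph(corr, threshold, mode="raw")
            dm = network_features.degree_maps(graph)
            for k in deg:
                deg[k].append(glm_activation.normalize_map(dm[k].astype(float)))
            if compute_heavy_maps:
                sm = network_features.strength_maps(corr)
                for k in ("strength", "strength_abs", "strength_pos"):
                    heavy[k].append(sm[k])
                abs_graph = network_features.build_graph(
                    corr, threshold, mode="absolute"
                )
                heavy["clustering"].append(network_features.clustering_map(abs_graph))
                heavy["local_efficiency"].append(
                    network_features.local_efficiency_map(abs_graph)
                )
            if compute_globals:
                globals_.append(network_features.global_features(graph))
            if keep_graphs:
                graphs.append((rec.group, graph))
            motion_summary.append(float(np.abs(np.diff(motion[:, 0])).mean()))

    n_vox = len(deg["degree_full"][0])
    fids = np.arange(n_vox)
    labels_arr = np.array(labels)
    sids = np.array(subject_ids)

    def table(vals, kind):
        return FeatureTable(
            values=np.vstack([np.asarray(v) for v in vals]),
            labels=labels_arr, subject_ids=sids, feature_ids=fids, kind=kind,
        )

    tables = {f"activation_{cid}_norm": table(act[cid], f"activation_{cid}_norm")
              for cid in contrast_ids}
    for k in deg:
        tables[f"{k}_norm"] = table(deg[k], f"{k}_norm")
    if compute_heavy_maps:
        for k in heavy:
            tables[k] = table(heavy[k], k)
    if n_edge_pairs:
        # pair features keep their linearized upper-triangle index as id
        pair_ids = (
            edge_pairs[:, 0] * (2 * n_vox - edge_pairs[:, 0] - 1) // 2
            + (edge_pairs[:, 1] - edge_pairs[:, 0] - 1)
        )
        tables["edge_weights"] = FeatureTable(
            values=np.vstack(edge_rows), labels=labels_arr, subject_ids=sids,
            feature_ids=pair_ids, kind="edge_weights",
        )
    return {
        "tables": tables,
        "graphs": graphs,
        "global_features": globals_,
        "motion_summary": np.array(motion_summary),
        "mean_abs_t": np.array(mean_tvals),
        "labels": labels_arr,
        "subject_ids": sids,
    }


def run_full_study(
    seed: int,
    n_per_group: int = 11,
    n_volumes: int = 200,
    k_grid: tuple[int, ...] = (10, 100, 500),
    stability_k: int = 100,
    cv_classifiers: tuple[str, ...] = ("gnb", "linear_margin"),
    gmrf_k: int | None = 100,
    gmrf_lambda: float = 0.01,
    cv_kinds: tuple[str, ...] = ("degree_full_norm", "activation_6_norm"),
    compute_heavy_maps: bool = True,
    n_edge_pairs: int = 5000,
    outdir: str | Path | None = None,
) -> dict:
    """Simulate a cohort and run every analysis stage.

    Stages: cohort simulation → GLM activation maps → network features →
    mass-univariate group statistics with FDR/Bonferroni → fold-wise
    selection stability → LOSOCV classification → distance-resolved group
    comparison → motion-confound check.  Fully deterministic given ``seed``.
    """
    t0 = time.time()
    timing = {}
    config = default_config(seed, n_per_group=n_per_group, n_volumes=n_volumes)
    records = generate_cohort(config)
    timing["simulate_s"] = round(time.time() - t0, 2)

    t1 = time.time()
    feats = build_feature_tables(records, compute_heavy_maps=compute_heavy_maps,
                                 n_edge_pairs=n_edge_pairs, edge_seed=seed)
    timing["features_s"] = round(time.time() - t1, 2)

    report: dict = {
        "seed": seed,
        "n_samples": len(feats["labels"]),
        "n_subjects": 2 * n_per_group,
        "baseline_accuracy": baseline_accuracy(feats["labels"]),
        "stats": {},
        "stability": {},
        "cv": {},
        "motion_check": {},
        "timing": timing,
    }

    t2 = time.time()
    support_v = config.activation_region[config.mask]
    for kind, table in feats["tables"].items():
        res = group_stats.two_sample_ttest(table)
        survivors = res.fdr_mask
        entry = {
            "n_features": int(table.n_features),
            "p_lt_0.05": int((res.pvalues < 0.05).sum()),
            "p_lt_0.01": int((res.pvalues < 0.01).sum()),
            "fdr_survivors": int(survivors.sum()),
            "bonferroni_survivors": int(res.bonferroni_mask.sum()),
        }
        if survivors.any() and table.n_features == support_v.size:
            entry["fdr_survivors_in_coupled_region"] = int(
                (survivors & support_v).sum()
            )
        report["stats"][kind] = entry
        mres = group_stats.motion_confound_check(table, feats["motion_summary"])
        report["motion_check"][kind] = int(mres.fdr_mask.sum())
    timing["stats_s"] = round(time.time() - t2, 2)

    t3 = time.time()
    for kind in cv_kinds:
        table = feats["tables"][kind]
        report["cv"][kind] = {}
        for clf in cv_classifiers:
            res = run_cv_experiment(table, clf, list(k_grid))
            report["cv"][kind][clf] = {
                str(k): {
                    "error": res.error[k],
                    "false_positive": res.false_positive[k],
                    "false_negative": res.false_negative[k],
                }
                for k in k_grid
            }
            if clf == "gnb" and stability_k in k_grid:
                report["stability"][kind] = res.stability(stability_k)
        if gmrf_k is not None:
            res = run_cv_experiment(table, "gmrf", [gmrf_k], {"lam": gmrf_lambda})
            report["cv"][kind]["gmrf"] = {
                str(gmrf_k): {
                    "error": res.error[gmrf_k],
                    "false_positive": res.false_positive[gmrf_k],
                    "false_negative": res.false_negative[gmrf_k],
                }
            }
    timing["cv_s"] = round(time.time() - t3, 2)

    t4 = time.time()
    left = config.factors[0].support & (np.indices(config.grid)[0] <
                                        config.grid[0] // 2)
    right = config.factors[0].support & ~left
    report["distance"] = distance_group_comparison(
        feats["graphs"],
        roi_pair=(left[config.mask], right[config.mask]),
    )
    timing["distance_s"] = round(time.time() - t4, 2)
    timing["total_s"] = round(time.time() - t0, 2)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "study_report.json").write_text(json.dumps(report, indent=2))
    return report
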