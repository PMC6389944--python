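"""Simulation studies validating the statistical pipeline.

Three study designs, each running the real analysis path on synthetic
cohorts:

* :func:`fwer_study` — family-wise error calibration of the max-|t|
  Freedman–Lane correction under a global null (all effect slopes zero);
* :func:`power_study` — recovery of injected penetrance-linked cingulum
  curvature and ICVF effects through the full simulate →
  re-parameterise → PCA → cluster → segment → descriptor → median →
  GLM + max-T path, including the penetrance-vs-binary model contrast;
* :func:`segmentation_study` — held-out bundle-labelling accuracy of the
  shape-cluster segmentation on a three-bundle fixture.

These are the package's own quality gates; they are what the test suite
asserts and what the acceptance script reports.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from cnvtract.pipeline import PipelineConfig, shape_stage, tractometry_stage
from cnvtract.shape import fit_shape_pca, project, cluster_weights, \
    train_bundle_map, segment_bundles
from cnvtract.simulate import (SimulationDesign, build_cohort,
                               simulate_bundle, simulate_cohort_dataset,
                               simulate_feature_table)
from cnvtract.stats import permutation_correct
from cnvtract.streamlines import Tractogram, streamlines_to_features
from cnvtract.tractometry import assemble_features

__all__ = ["fwer_study", "power_study", "segmentation_study"]


def fwer_study(n_replicates: int = 200, B: int = 1000, n_features: int = 19,
               alpha: float = 0.05, seed: int = 0, predictor: str = "P_DD",
               ) -> dict[str, Any]:
    """Family-wise error rate of the max-|t| correction under the null.

    Each replicate draws a fresh 36-subject cohort and a feature family
    with nuisance (age/gender/TBV/motion) structure but a zero penetrance
    slope, then asks whether any corrected p in the family falls below
    ``alpha``. A calibrated procedure rejects in ~``alpha`` of
    replicates.
    """
    hits = 0
    for r in range(n_replicates):
        design = SimulationDesign(seed=seed + 7919 * (r + 1))
        cohort = build_cohort(design)
        Y = simulate_feature_table(cohort, n_features, effect_slope=0.0,
                                   seed=seed + 104729 * (r + 1))
        res = permutation_correct(Y, cohort, predictor, B=B,
                                  seed=seed + 1299709 * (r + 1),
                                  diffusion_derived=True, family_id="null")
        if min(x.p_corr for x in res) <= alpha:
            hits += 1
    return {"fwer": hits / n_replicates, "alpha": alpha,
            "n_replicates": n_replicates, "B": B, "n_features": n_features}


def power_study(n_cohorts: int = 50, seed: int = 0, alpha: float = 0.05,
                n_streamlines: int = 30, n_clusters: int = 40,
                B: int = 500) -> dict[str, Any]:
    """Recovery of the injected penetrance effects over simulated cohorts.

    For each cohort the full pipeline runs at desk scale (four bundle
    templates, ``n_streamlines`` per bundle, 7-component shape basis,
    ``n_clusters`` k-means clusters) and three events are recorded:

    * some dorsal-cingulum shape descriptor reaches ``p_corr <= alpha``
      for P_DD within the shape-descriptor family;
    * the dorsal-cingulum ICVF median reaches ``p_corr <= alpha`` within
      the ICVF family;
    * the penetrance model beats the binary carrier model on |t| for the
      cingulum ICVF median (the dose–response contrast).
    """
    cfg = PipelineConfig.from_profile(
        "desk", seed=seed, n_clusters=n_clusters, n_permutations=max(B, 100),
        metrics=("ICVF",), design={"n_streamlines": n_streamlines})
    hit_shape = hit_icvf = hit_contrast = 0
    t_pen: list[float] = []
    t_bin: list[float] = []
    for r in range(n_cohorts):
        cfg_r = PipelineConfig.from_profile(
            "desk", seed=seed + 6151 * (r + 1), n_clusters=n_clusters,
            n_permutations=max(B, 100), metrics=("ICVF",),
            design={"n_streamlines": n_streamlines})
        dataset = simulate_cohort_dataset(cfg_r.build_design())
        shape_info = shape_stage(dataset, cfg_r)
        tracto = tractometry_stage(dataset, shape_info["segmented"], cfg_r)
        fm = assemble_features(shape_info["descriptors"], tracto["volumes"],
                               tracto["medians"], metrics=cfg_r.metrics,
                               n_shape_components=shape_info["model"].n_components)
        cohort = dataset.cohort
        shape_cols = fm.data[fm.family_columns("shape")]
        res_shape = permutation_correct(shape_cols, cohort, "P_DD", B=B,
                                        seed=cfg_r.seed + 1,
                                        diffusion_derived=True,
                                        family_id="shape")
        cing = [x for x in res_shape
                if x.feature.startswith("cingulum_dorsal_L|")]
        if cing and min(x.p_corr for x in cing) <= alpha:
            hit_shape += 1
        icvf_cols = fm.data[fm.family_columns("microstructure:ICVF")]
        res_icvf = permutation_correct(icvf_cols, cohort, "P_DD", B=B,
                                       seed=cfg_r.seed + 2,
                                       diffusion_derived=True,
                                       family_id="microstructure:ICVF")
        target = [x for x in res_icvf if x.feature == "cingulum_dorsal_L|ICVF"]
        if target and target[0].p_corr <= alpha:
            hit_icvf += 1
        res_bin = permutation_correct(icvf_cols, cohort, "carrier", B=B,
                                      seed=cfg_r.seed + 3,
                                      diffusion_derived=True,
                                      family_id="microstructure:ICVF")
        tb = [x for x in res_bin if x.feature == "cingulum_dorsal_L|ICVF"]
        if target and tb:
            t_pen.append(abs(target[0].t))
            t_bin.append(abs(tb[0].t))
            if abs(target[0].t) > abs(tb[0].t):
                hit_contrast += 1
    return {"power_shape": hit_shape / n_cohorts,
            "power_icvf": hit_icvf / n_cohorts,
            "frac_penetrance_gt_binary": hit_contrast / n_cohorts,
            "median_abs_t_penetrance": float(np.median(t_pen)),
            "median_abs_t_binary": float(np.median(t_bin)),
            "n_cohorts": n_cohorts, "alpha": alpha, "B": B}


def segmentation_study(seed: int = 0, n_train_subjects: int = 6,
                       n_test_subjects: int = 4, n_streamlines: int = 30,
                       n_clusters: int = 30) -> dict[str, Any]:
    """Held-out segmentation accuracy on a three-bundle synthetic fixture.

    A shape model, cluster model and cluster→bundle map are trained on
    labelled bundles from one set of synthetic subjects; streamlines
    from fresh subjects (new noise realisations) are then segmented and
    compared with their generating labels.
    """
    templates = ("cingulum_dorsal_L", "cc_body", "uncinate_L")

    def _make(design: SimulationDesign, n_subj: int):
        cohort = build_cohort(design).iloc[:n_subj]
        sls, labels = [], []
        for sid, row in cohort.iterrows():
            for tpl in templates:
                bundle = simulate_bundle(tpl, row, design, subject_id=sid)
                sls.extend(bundle)
                labels.extend([tpl] * len(bundle))
        return sls, labels

    train_design = SimulationDesign(seed=seed, bundle_templates=templates,
                                    n_streamlines=n_streamlines)
    test_design = SimulationDesign(seed=seed + 1, bundle_templates=templates,
                                   n_streamlines=n_streamlines)
    train_sls, train_labels = _make(train_design, n_train_subjects)
    test_sls, test_labels = _make(test_design, n_test_subjects)

    X = streamlines_to_features(train_sls)
    model = fit_shape_pca(X, n_components=7)
    W = project(model, X)
    clusters = cluster_weights(W, K=min(n_clusters, len(W) // 10), seed=seed)
    train_bundle_map(clusters, W, train_labels)
    segmented = segment_bundles(Tractogram(streamlines=test_sls), model, clusters)
    correct = total = 0
    for label, idxs in segmented.items():
        for i in idxs:
            total += 1
            correct += label == test_labels[i]
    return {"accuracy": correct / total, "n_test_streamlines": total,
            "n_clusters": clusters.n_clusters}
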