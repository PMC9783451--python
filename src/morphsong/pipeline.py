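"""End-to-end orchestration: simulate -> extract -> cluster -> report.

The pipeline mirrors the study design: synthesize (or load) a cohort,
extract the nine song characteristics per recording and the wing
measurements per specimen, assemble the complete-case scaled trait matrix,
discover morphs by Ward.D2 + gap statistic, classify any individuals that
failed the complete-case filter by nearest centroid, compute the
within-morph form-function correlation grid with its decoupling summary,
and run the receiver-side analyses (phonotaxis contrasts, detectability
margins). Every stage writes plain files under the output directory and
the report records all parameters and seeds.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from morphsong import audio_features as af
from morphsong import formfunction_stats as ff
from morphsong import morph_clustering as mc
from morphsong import receiver_models as rm
from morphsong import synthetic_cohort as sc
from morphsong import wing_morphometrics as wm

__all__ = ["PipelineConfig", "run_pipeline", "cohort_feature_table"]

log = logging.getLogger("morphsong")


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "morphsong_run"
    seed: int = 42
    n_individuals: int = 59
    morph_proportions: dict = field(
        default_factory=lambda: {"ancestral": 0.40, "purring": 0.33, "rattling": 0.27}
    )
    sample_rate: float = 44100.0
    duration_s: float = 0.5
    window_size: int = 256
    band_edges_hz: tuple = af.DEFAULT_BAND_EDGES_HZ
    include_courtship: bool = True
    k_max: int = 10
    gap_B: int = 50
    gap_rule: str = "firstSEmax"
    diagnostic_traits: tuple = mc.DEFAULT_DIAGNOSTIC_TRAITS
    threshold_curve_csv: str | None = None  # None -> packaged synthetic curve
    song_spl_offset_db: float = 70.0  # maps dBFS to a nominal dB SPL scale
    run_receiver: bool = True
    n_females: int = 30


def cohort_feature_table(
    cohort: sc.CohortData, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract all features of a cohort.

    Returns ``(song_features, wing_features)`` tidy frames; wing shape
    scores come from PCA of the GPA-aligned cohort.
    """
    song_config = af.SongAnalysisConfig(
        window_size=config.window_size,
        bands=af.FrequencyBands(config.band_edges_hz),
    )
    songs = []
    for rec in cohort.recordings:
        if not config.include_courtship and rec.song_type == "courtship":
            continue
        songs.append(af.extract_song_features(rec, song_config))
    song_df = af.features_to_frame(songs)

    gpa = wm.generalized_procrustes(cohort.wings)
    scores, _, _ = wm.shape_pca(gpa, n_components=10)
    flags = cohort.flags.set_index("individual_id")
    wing_feats = []
    for cfg_w, row_scores in zip(cohort.wings, scores):
        frow = flags.loc[cfg_w.individual_id]
        wing_feats.append(
            wm.extract_wing_features(
                cfg_w,
                scraper_present=bool(frow["scraper"]),
                mirror_present=bool(frow["mirror"]),
                file_gaps_present=bool(frow["file_gaps"]),
                shape_scores=tuple(row_scores),
            )
        )
    wing_df = wm.wing_features_frame(wing_feats)
    return song_df, wing_df


def _individual_feature_table(
    song_df: pd.DataFrame, wing_df: pd.DataFrame
) -> pd.DataFrame:
    """Wide per-individual table: calling_*/courtship_* song + wing columns."""
    wide = song_df.pivot_table(
        index="individual_id",
        columns="song_type",
        values=list(mc.SONG_TRAITS),
        aggfunc="first",
    )
    wide.columns = [f"{st}_{trait}" for trait, st in wide.columns]
    return wide.join(wing_df.set_index("individual_id"), how="outer")


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return _round_floats(obj.item(), ndigits)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages and write a reproducible report bundle.

    Raises with the failing stage named; outputs written before a failure
    are retained for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _round_floats(vars(config).copy()), "stages": []}
    report["config"]["band_edges_hz"] = list(config.band_edges_hz)
    report["config"]["diagnostic_traits"] = list(config.diagnostic_traits)

    stage = "simulate"
    try:
        spec = sc.CohortSpec(
            n_individuals=config.n_individuals,
            morph_proportions=config.morph_proportions,
            seed=config.seed,
            sample_rate=config.sample_rate,
            duration_s=config.duration_s,
        )
        cohort = sc.generate_cohort(spec)
        cohort.metadata.to_csv(out / "metadata.csv", index=False)
        cohort.truth.to_csv(out / "ground_truth.csv", index=False)
        cohort.flags.to_csv(out / "flags.csv", index=False)
        report["stages"].append(stage)
        log.info("simulated cohort: n=%d seed=%d", spec.n_individuals, spec.seed)

        stage = "extract"
        song_df, wing_df = cohort_feature_table(cohort, config)
        features = _individual_feature_table(song_df, wing_df)
        song_df.to_csv(out / "song_features.csv", index=False)
        wing_df.to_csv(out / "wing_features.csv", index=False)
        features.to_csv(out / "all_features.csv")
        report["stages"].append(stage)

        stage = "cluster"
        if config.include_courtship:
            matrix = mc.assemble_trait_matrix(song_df, wing_df)
            tree = mc.ward_cluster(matrix)
            gap = mc.gap_statistic(
                matrix,
                k_max=config.k_max,
                B=config.gap_B,
                seed=config.seed,
                rule=config.gap_rule,
            )
            (out / "dendrogram.nwk").write_text(mc.to_newick(tree))
            (out / "merge_tree.json").write_text(mc.merges_to_json(tree))
            cluster_labels = {
                ind: f"cluster{lab}"
                for ind, lab in zip(matrix.individuals, gap.labels_at_best_k)
            }
            named = _name_clusters(features, cluster_labels)
            training_ids = list(matrix.individuals)
            assignments = [
                mc.MorphAssignment(ind, named[ind], "clustered")
                for ind in training_ids
            ]
            remaining = features.index.difference(training_ids)
            if len(remaining):
                assignments += mc.classify_nearest_centroid(
                    features.loc[remaining],
                    features.loc[training_ids],
                    pd.Series({i: named[i] for i in training_ids}),
                    diagnostic_traits=config.diagnostic_traits,
                )
            report["gap"] = {
                "best_k": int(gap.best_k),
                "k_candidates": list(gap.k_candidates),
                "gap": [float(g) for g in gap.gap],
                "s_k": [float(s) for s in gap.s_k],
                "rule": gap.rule,
                "B": gap.B,
            }
            report["complete_case_n"] = len(matrix.individuals)
            report["dropped_individuals"] = list(matrix.dropped)
        else:
            warnings.warn(
                "courtship songs disabled: no complete-case matrix; falling "
                "back to rule classification against archetype centroids",
                stacklevel=2,
            )
            log.warning("classification-only mode (no courtship songs)")
            centroids, morph_labels = _archetype_training_table(config)
            assignments = mc.classify_nearest_centroid(
                features,
                centroids,
                morph_labels,
                diagnostic_traits=config.diagnostic_traits,
            )
            report["gap"] = None
        assign_df = mc.assignments_frame(assignments).set_index("individual_id")
        assign_df.to_csv(out / "morphs.csv")
        counts = assign_df["morph"].value_counts().sort_index()
        report["morph_counts"] = {str(k): int(v) for k, v in counts.items()}
        report["stages"].append(stage)

        stage = "formfunction"
        grid, summary = ff.formfunction_report(
            features, assign_df["morph"], alpha=0.05
        )
        grid.to_csv(out / "formfunction_grid.csv", index=False)
        (out / "formfunction_summary.json").write_text(
            json.dumps(_round_floats(summary), sort_keys=True, indent=1)
        )
        report["decoupling"] = _round_floats(summary)
        report["stages"].append(stage)

        if config.run_receiver:
            stage = "receiver"
            trials = sc.generate_phonotaxis_trials(
                n_females=config.n_females, seed=config.seed
            )
            trials.to_csv(out / "phonotaxis_trials.csv", index=False)
            fit, levels = rm.fit_phonotaxis(trials, outcome="responded")
            contrasts = rm.pairwise_contrasts(fit, levels)
            contrasts.to_csv(out / "phonotaxis_contrasts.csv", index=False)
            report["phonotaxis"] = {
                "levels": levels,
                "converged": fit.converged,
                "contrasts": _round_floats(
                    contrasts.to_dict(orient="records")
                ),
            }
            curve = (
                rm.ThresholdCurve.from_csv(config.threshold_curve_csv)
                if config.threshold_curve_csv
                else rm.synthetic_threshold_curve()
            )
            report["detectability"] = _detectability_summary(
                features, assign_df["morph"], curve, config
            )
            report["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report_text = json.dumps(_round_floats(report), sort_keys=True, indent=1)
    (out / "report.json").write_text(report_text)
    (out / "run_log.txt").write_text(
        f"seed={config.seed}\nstages={report['stages']}\n"
    )
    return report


def _name_clusters(features: pd.DataFrame, cluster_labels: dict) -> dict:
    """Map anonymous cluster ids to morph names via their phenotype.

    The quietest cluster with the highest evenness is purring; among the
    rest, file gaps mark rattling and the remainder is ancestral. Falls
    back to generic names if the heuristics collide.
    """
    labels = pd.Series(cluster_labels)
    means = features.loc[labels.index].groupby(labels).agg(
        amp=("calling_amplitude_db", "mean"),
        gaps=("file_gaps_present", "mean"),
        mirror=("mirror_present", "mean"),
    )
    names = {}
    purring = means["mirror"].idxmin() if means["mirror"].min() < 0.5 else None
    if purring is not None:
        names[purring] = "purring"
    rest = means.drop(index=[c for c in [purring] if c is not None])
    if len(rest):
        rattling = rest["gaps"].idxmax() if rest["gaps"].max() > 0.5 else None
        if rattling is not None:
            names[rattling] = "rattling"
        for c in rest.index:
            if c not in names:
                names[c] = "ancestral" if "ancestral" not in names.values() else str(c)
    return {ind: names.get(lab, str(lab)) for ind, lab in labels.items()}


def _archetype_training_table(config: PipelineConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic diagnostic centroids straight from archetype parameters.

    Used only in classification-only mode; an emulation of defining morph
    criteria without a clustered training sample.
    """
    rows, labels = {}, {}
    for name, arch in sc.default_archetypes().items():
        for rep, scraper in enumerate((True, False)):
            if scraper and arch.scraper_present_prob == 0:
                continue
            if not scraper and arch.scraper_present_prob == 1:
                continue
            carrier = (
                arch.scraperless_carrier_hz_mean
                if (not scraper and arch.scraperless_carrier_hz_mean)
                else arch.carrier_hz_mean
            )
            rid = f"{name}_{rep}"
            rows[rid] = {
                "mirror_present": arch.mirror_present_prob,
                "harp_width": arch.harp_width_mean,
                "calling_amplitude_db": arch.amplitude_db_mean,
                "calling_frequency_evenness": -0.37 + 0.3 * arch.noise_mix_mean,
                "calling_dominant_frequency": carrier,
                "file_gaps_present": float(arch.file_gaps_present),
            }
            labels[rid] = name
    return pd.DataFrame(rows).T, pd.Series(labels)


def _detectability_summary(
    features: pd.DataFrame, morphs: pd.Series, curve: rm.ThresholdCurve, config: PipelineConfig
) -> dict:
    """Scraper-split purring detectability on the supplied threshold curve."""
    purring = features.loc[morphs.index[morphs == "purring"]]
    out: dict = {"curve_domain_hz": list(curve.domain)}
    if not len(purring):
        return out
    lo, hi = curve.domain
    for label, mask in (
        ("scraper_present", purring["scraper_present"] == 1),
        ("scraper_absent", purring["scraper_present"] == 0),
    ):
        sub = purring.loc[mask, "calling_dominant_frequency"].clip(lo, hi)
        if len(sub):
            med = float(sub.median())
            spl = float(
                purring.loc[mask, "calling_amplitude_db"].median()
                + config.song_spl_offset_db
            )
            out[label] = {
                "n": int(mask.sum()),
                "median_dominant_frequency_hz": med,
                "required_amplitude_db": rm.required_amplitude(med, curve),
                "median_margin_db": rm.detectability_margin(med, spl, curve),
            }
    if "scraper_present" in out and "scraper_absent" in out:
        out["threshold_difference_db"] = rm.threshold_difference(
            out["scraper_absent"]["median_dominant_frequency_hz"],
            out["scraper_present"]["median_dominant_frequency_hz"],
            curve,
        )
    return out
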