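"""The end-to-end subtyping model and its results object.

:class:`MethylationSubtypeModel` bundles a beta-value matrix, a clinical
table and a probe manifest; :meth:`fit` runs the full discovery
pipeline — probe/sample filtering, KNN imputation, balanced train/test
split, two-stage Cox screening on the train half, consensus clustering
with CDF/delta-area K selection, survival and clinical
characterization, entropy-based specific-CpG calling, Gaussian naive
Bayes classifier with cross-validation, and test-set subtype
assignment — and returns a :class:`SubtypeResults` carrying every
intermediate product plus a printable ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .classify import (CVResult, NBModel, TestAssignment, assign_test_set,
                       cross_validate, fit_nb, multiclass_auc, predict_nb)
from .config import PipelineConfig
from .consensus import ConsensusResult, run_consensus
from .preprocess import (FilterReport, SplitReport, filter_probes,
                         filter_samples, knn_impute, stratified_split)
from .screening import screen
from .specific import annotate_genes, find_specific_cpgs
from .survival import characterize_clusters

logger = logging.getLogger(__name__)

STAGE_ORDER = ["preprocess", "split", "screen", "consensus", "characterize",
               "specific", "classify", "assign_test"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SubtypeResults:
    """Everything the fitted subtyping pipeline produced."""

    config: PipelineConfig
    filter_report: FilterReport
    split_report: SplitReport
    train_ids: list[str]
    test_ids: list[str]
    screen_table: pd.DataFrame
    selected_probes: list[str]
    consensus: ConsensusResult
    train_labels: pd.Series
    train_curves: dict
    train_logrank: object
    train_associations: pd.DataFrame
    specific_calls: pd.DataFrame
    entropy_threshold: float
    cluster_means: pd.DataFrame
    gene_annotation: object
    nb_model: NBModel
    cv: CVResult
    cv_auc: float
    train_posteriors: pd.DataFrame
    test_assignment: TestAssignment
    imputed: pd.DataFrame = field(repr=False, default=None)
    warnings: list[str] = field(default_factory=list)

    @property
    def chosen_k(self) -> int:
        return self.consensus.chosen_k

    def summary(self) -> str:
        lines = [
            "DNA methylation prognostic subtyping",
            "=" * 44,
            f"samples (train / test):      {len(self.train_ids)} / {len(self.test_ids)}",
            f"probes after filtering:      {self.filter_report.n_kept}"
            f" (removed {self.filter_report.n_input - self.filter_report.n_kept})",
            f"univariate Cox hits:         {int(self.screen_table['selected_uni'].sum())}",
            f"screened prognostic CpGs:    {len(self.selected_probes)}",
            f"chosen number of subtypes K: {self.chosen_k}",
            "cluster sizes:               "
            + ", ".join(f"{c}: {n}" for c, n in
                        self.train_labels.value_counts().sort_index().items()),
            f"train log-rank:              chi2 = {self.train_logrank.statistic:.2f},"
            f" df = {self.train_logrank.df}, p = {self.train_logrank.p:.3g}",
            f"specific CpGs called:        {len(self.specific_calls)}"
            f" (entropy < {self.entropy_threshold:.4f} bits)",
            f"annotated genes (promoter):  {len(self.gene_annotation.genes)}"
            f" ({len(self.gene_annotation.promoter_genes)})",
            f"{self.cv_nfolds()}-fold CV accuracy:         "
            f"{100 * self.cv.accuracy:.1f}%",
            f"Hand-Till multiclass AUC:    {self.cv_auc:.4f}",
            f"test-set log-rank:           chi2 = "
            f"{self.test_assignment.test_logrank.statistic:.2f}, p = "
            f"{self.test_assignment.test_logrank.p:.3g}",
        ]
        if self.warnings:
            lines.append("warnings: " + "; ".join(self.warnings))
        return "\n".join(lines)

    def cv_nfolds(self) -> int:
        return int(self.cv.folds.max()) + 1

    # ------------------------------------------------------------------
    def save(self, outdir) -> Path:
        """Write every artifact as deterministic plain text under outdir."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.filter_report.removed.to_csv(out / "probe_removal.tsv", sep="\t",
                                          index=False, lineterminator="\n")
        msio.write_json(
            {"train_ids": self.train_ids, "test_ids": self.test_ids,
             "balance_pvalues": self.split_report.pvalues,
             "attempts": self.split_report.attempts,
             "passed": self.split_report.passed},
            out / "split.json")
        self.screen_table.to_csv(out / "screen.tsv", sep="\t", na_rep="NA",
                                 lineterminator="\n")
        cons_dir = out / "consensus"
        cons_dir.mkdir(exist_ok=True)
        for k, M in self.consensus.matrices.items():
            pd.DataFrame(M, index=self.train_ids, columns=self.train_ids
                         ).to_csv(cons_dir / f"consensus_k{k}.tsv", sep="\t",
                                  lineterminator="\n")
        pd.DataFrame(
            {"k": self.consensus.k_range,
             "area": [self.consensus.areas[k] for k in self.consensus.k_range],
             "delta_area": [self.consensus.deltas[k]
                            for k in self.consensus.k_range],
             "min_cluster_consensus": [
                 min(self.consensus.cluster_scores[k].values())
                 for k in self.consensus.k_range]}
        ).to_csv(out / "cdf_area.tsv", sep="\t", index=False,
                 lineterminator="\n")
        msio.write_json(self.consensus.trace, out / "k_selection.json")
        self.train_labels.rename("cluster").to_csv(
            out / "train_labels.tsv", sep="\t", lineterminator="\n")
        km_rows = []
        for c, curve in self.train_curves.items():
            frame = curve.as_frame()
            frame.insert(0, "cluster", c)
            km_rows.append(frame)
        pd.concat(km_rows, ignore_index=True).to_csv(
            out / "train_km.tsv", sep="\t", index=False, lineterminator="\n")
        msio.write_json(
            {"train": {"statistic": self.train_logrank.statistic,
                       "df": self.train_logrank.df, "p": self.train_logrank.p},
             "test": {"statistic": self.test_assignment.test_logrank.statistic,
                      "df": self.test_assignment.test_logrank.df,
                      "p": self.test_assignment.test_logrank.p},
             "cross_set_per_cluster": {
                 str(c): {"statistic": r.statistic, "p": r.p}
                 for c, r in self.test_assignment.cross_set_logrank.items()},
             "cross_set_skipped": self.test_assignment.skipped_clusters},
            out / "logrank.json")
        self.train_associations.to_csv(out / "train_associations.tsv",
                                       sep="\t", na_rep="NA",
                                       lineterminator="\n")
        self.cluster_means.to_csv(out / "cluster_means.tsv", sep="\t",
                                  lineterminator="\n")
        self.specific_calls.to_csv(out / "specific_calls.tsv", sep="\t",
                                   lineterminator="\n")
        (out / "specific_genes.txt").write_text(
            "\n".join(self.gene_annotation.genes) + "\n")
        (out / "promoter_genes.txt").write_text(
            "\n".join(self.gene_annotation.promoter_genes) + "\n")
        msio.write_json(self.nb_model.to_dict(), out / "nb_model.json")
        msio.write_json(
            {"cv_accuracy": self.cv.accuracy,
             "cv_fold_accuracy": self.cv.fold_accuracy,
             "cv_mean_fold_accuracy": float(np.mean(self.cv.fold_accuracy)),
             "hand_till_auc": self.cv_auc,
             "entropy_threshold_bits": self.entropy_threshold,
             "chosen_k": self.chosen_k,
             "n_specific_cpgs": len(self.specific_calls),
             "n_genes": len(self.gene_annotation.genes),
             "n_promoter_genes": len(self.gene_annotation.promoter_genes)},
            out / "metrics.json")
        self.test_assignment.labels.rename("cluster").to_csv(
            out / "test_labels.tsv", sep="\t", lineterminator="\n")
        self.test_assignment.posteriors.to_csv(out / "test_posteriors.tsv",
                                               sep="\t", lineterminator="\n")
        msio.write_json(
            {"config": self.config.to_dict(), "stages": STAGE_ORDER,
             "seed": self.config.seed, "warnings": self.warnings},
            out / "run_manifest.json")
        (out / "summary.txt").write_text(self.summary() + "\n")
        return out


class MethylationSubtypeModel:
    """Prognostic methylation subtyping of a tumor cohort.

    Parameters
    ----------
    methylation : probes x samples beta-value DataFrame (NaN = missing).
    clinical : per-sample clinical DataFrame (see :mod:`methsubtypes.io`).
    manifest : per-probe manifest DataFrame.
    config : :class:`PipelineConfig`; defaults to the published protocol.
    """

    def __init__(self, methylation: pd.DataFrame, clinical: pd.DataFrame,
                 manifest: pd.DataFrame,
                 config: PipelineConfig | None = None):
        self.methylation = methylation
        self.clinical = clinical
        self.manifest = manifest
        self.config = config or PipelineConfig()
        self.config.validate()

    @classmethod
    def from_files(cls, methylation_tsv, clinical_tsv, manifest_csv,
                   config: PipelineConfig | None = None
                   ) -> "MethylationSubtypeModel":
        return cls(msio.read_methylation_tsv(methylation_tsv),
                   msio.read_clinical_tsv(clinical_tsv),
                   msio.read_manifest(manifest_csv), config)

    @classmethod
    def from_synthetic(cls, spec=None, config: PipelineConfig | None = None):
        """Build from a simulated cohort; returns (model, cohort)."""
        from .synthetic import CohortSpec, generate_cohort
        spec = spec or CohortSpec()
        cohort = generate_cohort(spec)
        model = cls(cohort.methylation, cohort.clinical, cohort.manifest,
                    config)
        return model, cohort

    # ------------------------------------------------------------------
    def fit(self) -> SubtypeResults:
        cfg = self.config
        warnings: list[str] = []
        stage = "preprocess"
        try:
            kept_samples = filter_samples(self.clinical,
                                          cfg.min_followup_days)
            clinical = self.clinical.loc[kept_samples]
            m = self.methylation[kept_samples]
            m, filt_report = filter_probes(m, self.manifest,
                                           cfg.max_missing_frac)
            m = knn_impute(m, k=cfg.knn_k)

            stage = "split"
            train_ids, test_ids, split_report = stratified_split(
                clinical, train_frac=cfg.train_frac, seed=cfg.seed,
                max_attempts=cfg.split_attempts)
            if not split_report.passed:
                warnings.extend(split_report.warnings)
            train_m, train_c = m[train_ids], clinical.loc[train_ids]
            test_m, test_c = m[test_ids], clinical.loc[test_ids]

            stage = "screen"
            screen_table = screen(train_m, train_c,
                                  alpha=cfg.alpha_univariate,
                                  q_cutoff=cfg.q_cutoff)
            selected = list(screen_table.index[screen_table["selected"]])
            min_probes = 2 * cfg.k_max
            if len(selected) < min_probes:
                ranked = screen_table.sort_values(
                    ["q", "p_uni"], kind="mergesort", na_position="last")
                selected = list(ranked.index[:min_probes])
                msg = (f"only {int(screen_table['selected'].sum())} probes "
                       f"passed the screen; using the {min_probes} "
                       f"best-ranked probes")
                warnings.append(msg)
                logger.warning(msg)

            stage = "consensus"
            k_range = range(cfg.k_min,
                            min(cfg.k_max, len(train_ids) - 1) + 1)
            consensus = run_consensus(
                train_m.loc[selected].T.to_numpy(), k_range,
                n_iter=cfg.n_consensus_iter,
                subsample_frac=cfg.subsample_frac,
                min_consensus=cfg.min_cluster_consensus,
                delta_tol=cfg.delta_tol, seed=cfg.seed,
                sample_ids=train_ids)
            train_labels = pd.Series(consensus.labels, index=train_ids,
                                     name="cluster")

            stage = "characterize"
            curves, logrank, assoc = characterize_clusters(train_labels,
                                                           train_c)

            stage = "specific"
            calls, threshold, cluster_means = find_specific_cpgs(
                train_m.loc[selected], train_labels, sd=cfg.entropy_sd,
                n_null=cfg.n_null, q=cfg.null_quantile, seed=cfg.seed)
            annotation = annotate_genes(calls, self.manifest)
            features = list(calls.index)
            if not features:
                msg = ("no specific CpGs called; classifier falls back to "
                       "all screened probes")
                warnings.append(msg)
                logger.warning(msg)
                features = selected

            stage = "classify"
            train_X = train_m.loc[features].T
            usable = train_labels.map(train_labels.value_counts()) >= 2
            if not usable.all():
                msg = (f"dropping {int((~usable).sum())} train samples in "
                       f"singleton clusters before classification")
                warnings.append(msg)
                logger.warning(msg)
            cv = cross_validate(train_X[usable], train_labels[usable],
                                n_folds=cfg.n_folds, seed=cfg.seed,
                                var_floor=cfg.var_floor)
            auc = multiclass_auc(cv.posteriors, train_labels[usable])
            nb_model = fit_nb(train_X[usable], train_labels[usable],
                              var_floor=cfg.var_floor)
            _, train_post = predict_nb(nb_model, train_X)

            stage = "assign_test"
            assignment = assign_test_set(nb_model, test_m.loc[features].T,
                                         test_c, train_clinical=train_c,
                                         train_labels=train_labels)
        except Exception as exc:  # annotate failures with the stage name
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError(stage, exc) from exc

        return SubtypeResults(
            config=cfg, filter_report=filt_report, split_report=split_report,
            train_ids=train_ids, test_ids=test_ids,
            screen_table=screen_table, selected_probes=selected,
            consensus=consensus, train_labels=train_labels,
            train_curves=curves, train_logrank=logrank,
            train_associations=assoc, specific_calls=calls,
            entropy_threshold=threshold, cluster_means=cluster_means,
            gene_annotation=annotation, nb_model=nb_model, cv=cv,
            cv_auc=auc, train_posteriors=train_post,
            test_assignment=assignment, imputed=m, warnings=warnings)


def run_pipeline(config: PipelineConfig, outdir, methylation=None,
                 clinical=None, manifest=None, cohort_spec=None
                 ) -> Path:
    """Run the full pipeline and write every artifact under ``outdir``.

    Either pass the three input frames/paths, or a
    :class:`~methsubtypes.synthetic.CohortSpec` to simulate the cohort
    first.  Fully deterministic given the config (and spec seed).
    """
    if cohort_spec is not None:
        model, cohort = MethylationSubtypeModel.from_synthetic(
            cohort_spec, config)
    else:
        if isinstance(methylation, (str, Path)):
            model = MethylationSubtypeModel.from_files(methylation, clinical,
                                                       manifest, config)
        else:
            model = MethylationSubtypeModel(methylation, clinical, manifest,
                                            config)
        cohort = None
    results = model.fit()
    out = results.save(outdir)
    if cohort is not None:
        msio.write_json(
            {"true_labels": cohort.true_labels.to_dict(),
             "true_specific": {str(c): [list(t) for t in calls]
                               for c, calls in cohort.true_specific.items()}},
            out / "truth.json")
    return out
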