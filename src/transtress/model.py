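"""Statsmodels-style front end: fit the whole transcriptional-stress
analysis to an adult/old EU-seq + RNAPII ChIP-seq dataset.

:class:`TranscriptionalStressModel` wraps a catalog plus replicate
profiles; :meth:`fit` runs background correction, the expressed-gene
filter, per-bin density change, length-class loss regression, stalling
estimation, gene-group classification, strand bias and exon-output
metrics, returning a :class:`TranscriptionalStressResults` with a
``summary()`` table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import classify, metrics, profiling, stalling, strand_bias
from .annotation import GeneCatalog
from .profiling import BinnedProfile
from .simulate import SimConfig, SimulatedDataset, simulate_dataset

log = logging.getLogger(__name__)


@dataclass
class TranscriptionalStressResults:
    """Estimates, uncertainties and per-gene tables from one fit."""

    model: "TranscriptionalStressModel"
    expressed_genes: set[str]
    density_change: metrics.DensityChange
    per_bin_pvalues: pd.DataFrame | None
    length_classes: metrics.LengthClasses
    class_decline: pd.DataFrame
    loss_slope_per_kb: float
    loss_slope_se: float
    stalling_estimate: stalling.StallingEstimate | None
    stalling_by_class: pd.DataFrame | None
    gene_groups: classify.GeneGroupLabels | None
    strand_bias_thirds: pd.Series | None
    strand_bias_by_class: pd.DataFrame | None
    exon_loss: pd.DataFrame | None
    ts_high: set[str]
    utr3_ratio: pd.Series | None
    nascent_output_fold: float
    recovered_vs_truth: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Transcriptional stress analysis (old vs adult)",
            "=" * 54,
            f"expressed genes (>=1 RPM all bins, both ages) : {len(self.expressed_genes)}",
            f"gene-body nascent-output fold (adult / old)   : {self.nascent_output_fold:.3f}",
            f"excess loss slope (% per kb)                  : "
            f"{self.loss_slope_per_kb:.3f} +/- {self.loss_slope_se:.3f}",
        ]
        if self.stalling_estimate is not None:
            est = self.stalling_estimate
            lines.append(
                f"nonproductive RNAPII in gene bodies (%)       : "
                f"{est.mean_percent:.1f} (s.d. {est.sd_percent:.1f}, n={est.n})"
            )
        if self.gene_groups is not None:
            counts = self.gene_groups.counts()
            lines.append("gene groups: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
        lines.append(f"TS-high genes (>1.5-fold exon loss)           : {len(self.ts_high)}")
        if self.strand_bias_thirds is not None:
            sb = self.strand_bias_thirds
            lines.append(
                "coding-strand fraction (old ChIP, by third)   : "
                + ", ".join(f"{v:.3f}" for v in sb)
            )
        lines.append("-" * 54)
        lines.append("per-class decline:")
        lines.append(
            self.class_decline[["n", "mean_length_kb", "decline_percent"]]
            .round(2)
            .to_string()
        )
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serializable summary of the headline numbers."""
        rep = {
            "n_expressed": len(self.expressed_genes),
            "nascent_output_fold": self.nascent_output_fold,
            "loss_slope_per_kb": self.loss_slope_per_kb,
            "loss_slope_se": self.loss_slope_se,
            "n_ts_high": len(self.ts_high),
            "class_decline": self.class_decline.reset_index().to_dict("records"),
        }
        if self.stalling_estimate is not None:
            rep["stalling_mean_percent"] = self.stalling_estimate.mean_percent
            rep["stalling_sd_percent"] = self.stalling_estimate.sd_percent
        if self.gene_groups is not None:
            rep["group_counts"] = self.gene_groups.counts().to_dict()
        if self.strand_bias_thirds is not None:
            rep["coding_strand_fraction_by_third"] = self.strand_bias_thirds.round(4).to_dict()
        if self.recovered_vs_truth:
            rep["recovered_vs_truth"] = self.recovered_vs_truth
        return rep

    def plot_density_change(self, ax=None):
        """Metagene curve of mean density change ± s.e.m. per bin."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(1, len(self.density_change.bin_mean) + 1)
        m = self.density_change.bin_mean.to_numpy()
        s = self.density_change.bin_sem.to_numpy()
        ax.plot(x, m, color="crimson", label="old / adult")
        ax.fill_between(x, m - s, m + s, color="crimson", alpha=0.3)
        ax.axhline(100, color="gray", ls="--", lw=0.8)
        ax.set_xlabel("gene-body bin (TSS → TTS)")
        ax.set_ylabel("density change (%)")
        ax.legend()
        return ax


class TranscriptionalStressModel:
    """The analysis pipeline as a fittable model.

    Parameters
    ----------
    catalog : GeneCatalog
        Filtered, non-overlapping genes (>= 10 kb).
    profiles : list of BinnedProfile
        Raw gene x k count matrices for EU (both groups, replicated)
        and optionally ChIP_total.
    strand_counts, exon_counts, exon_lengths :
        Optional stranded ChIP matrices and exon-region count tables,
        as produced by the simulator or external pipelines.
    """

    def __init__(
        self,
        catalog: GeneCatalog,
        profiles: list[BinnedProfile],
        strand_counts: dict | None = None,
        exon_counts: dict | None = None,
        exon_lengths: pd.DataFrame | None = None,
        input_profiles: list[BinnedProfile] | None = None,
        ground_truth: dict | None = None,
    ) -> None:
        self.catalog = catalog
        self.profiles = profiles
        self.strand_counts = strand_counts or {}
        self.exon_counts = exon_counts or {}
        self.exon_lengths = exon_lengths
        self.input_profiles = input_profiles or []
        self.ground_truth = ground_truth or {}
        ks = {p.k for p in profiles}
        if len(ks) != 1:
            raise ValueError(f"profiles disagree on bin count: {ks}")
        self.k = ks.pop()

    @classmethod
    def from_simulation(cls, config: SimConfig) -> "TranscriptionalStressModel":
        return cls.from_dataset_object(simulate_dataset(config))

    @classmethod
    def from_dataset_object(cls, ds: SimulatedDataset) -> "TranscriptionalStressModel":
        return cls(
            catalog=ds.catalog,
            profiles=ds.profiles,
            strand_counts=ds.strand_counts,
            exon_counts=ds.exon_counts,
            exon_lengths=ds.exon_lengths,
            ground_truth=ds.ground_truth,
        )

    @classmethod
    def from_directory(cls, path) -> "TranscriptionalStressModel":
        from .simulate import read_dataset

        return cls.from_dataset_object(read_dataset(path))

    # -- pipeline ----------------------------------------------------------

    def _corrected(self, profiles: list[BinnedProfile]) -> list[BinnedProfile]:
        by_group_input = {p.group: p for p in self.input_profiles}
        out = []
        for p in profiles:
            out.append(
                profiling.subtract_background(
                    p, self.catalog, input_profile=by_group_input.get(p.group)
                )
            )
        return out

    def fit(
        self,
        min_rpm: float = 1.0,
        n_clusters: int = 8,
        seed: int = 0,
        delta: float = 0.26,
        ts_fold: float = 1.5,
        length_class_mode: str = "quantile6",
        run_ttests: bool = True,
    ) -> TranscriptionalStressResults:
        eu = self._corrected([p for p in self.profiles if p.assay == "EU"])
        chip_raw = [p for p in self.profiles if p.assay.startswith("ChIP")]
        chip = self._corrected(chip_raw) if chip_raw else []

        expressed = profiling.expressed_gene_set(eu, min_rpm=min_rpm)
        if not expressed:
            raise ValueError("no expressed genes at the requested RPM threshold")
        exp_idx = pd.Index(sorted(expressed), name="gene_id")
        lengths = pd.Series(self.catalog.lengths(), name="length").reindex(exp_idx)

        eu_adult = profiling.group_mean_rpm(eu, "EU", "adult").loc[exp_idx]
        eu_old = profiling.group_mean_rpm(eu, "EU", "old").loc[exp_idx]
        change = metrics.density_change_percent(eu_old, eu_adult)

        pvals = None
        if run_ttests:
            adult_reps = [m.loc[exp_idx] for m in profiling.replicate_rpm(eu, "EU", "adult")]
            old_reps = [m.loc[exp_idx] for m in profiling.replicate_rpm(eu, "EU", "old")]
            if min(len(adult_reps), len(old_reps)) >= 2:
                pvals = per_bin_ttest(old_reps, adult_reps)

        classes = metrics.length_classes(lengths, mode=length_class_mode)
        class_decline = metrics.gene_body_decline_by_class(change, lengths, classes)
        slope, slope_se = metrics.per_kb_loss_slope(class_decline)

        # absolute nascent output over the whole catalog (the global loss
        # that per-library RPM scaling would otherwise hide)
        adult_total = sum(p.data.to_numpy().sum() for p in eu if p.group == "adult")
        old_total = sum(p.data.to_numpy().sum() for p in eu if p.group == "old")
        n_a = sum(1 for p in eu if p.group == "adult")
        n_o = sum(1 for p in eu if p.group == "old")
        fold = (adult_total / n_a) / (old_total / n_o) if old_total else float("nan")

        stall_est = stall_by_class = groups = None
        sb_thirds = sb_class = None
        if chip:
            chip_assay = chip[0].assay
            chip_adult = profiling.group_mean_rpm(chip, chip_assay, "adult").loc[exp_idx]
            chip_old_reps = [
                m.loc[exp_idx] for m in profiling.replicate_rpm(chip, chip_assay, "old")
            ]
            ep = metrics.elongation_phase
            stall_est = stalling.estimate_stalling(
                old_eu=ep(eu_old).sum(axis=1),
                adult_eu=ep(eu_adult).sum(axis=1),
                adult_chip=ep(chip_adult).sum(axis=1),
                observed_old_chip=[ep(m).sum(axis=1) for m in chip_old_reps],
            )
            stall_by_class = stalling.stalling_by_length_class(stall_est, classes)

            chip_old = profiling.group_mean_rpm(chip, chip_assay, "old").loc[exp_idx]
            eu3 = metrics.three_bin_heatmap(ep(eu_old), ep(eu_adult))
            chip3 = metrics.three_bin_heatmap(ep(chip_old), ep(chip_adult))
            if n_clusters <= len(exp_idx):
                clusters, centroids = classify.cluster_genes(
                    eu3, chip3, n_clusters=n_clusters, seed=seed
                )
                groups = classify.assign_groups(clusters, centroids, delta=delta)

            if self.strand_counts:
                old_ids = [p.sample_id for p in chip_raw if p.group == "old"]
                cods = [self.strand_counts[s][0].loc[exp_idx] for s in old_ids if s in self.strand_counts]
                tems = [self.strand_counts[s][1].loc[exp_idx] for s in old_ids if s in self.strand_counts]
                if cods:
                    cod = sum(c for c in cods)
                    tem = sum(t for t in tems)
                    sb_thirds = strand_bias.strand_bias_by_position(cod, tem, n_bins=3)
                    sb_class = strand_bias.strand_bias_by_length_class(cod, tem, classes)
        elif self.profiles and not chip_raw:
            log.info("no ChIP profiles: stalling, classification and strand bias skipped")

        exon_loss = utr3 = None
        ts_high: set[str] = set()
        if self.exon_counts and self.exon_lengths is not None:
            by_group: dict[str, list[pd.DataFrame]] = {}
            for p in self.profiles:
                if p.assay == "EU" and p.sample_id in self.exon_counts:
                    by_group.setdefault(p.group, []).append(
                        self.exon_counts[p.sample_id].loc[exp_idx]
                    )
            if set(by_group) == {"adult", "old"}:
                exon_loss = metrics.first_last_exon_loss(
                    by_group, self.exon_lengths.loc[exp_idx]
                )
                ts_high = metrics.select_ts_high(exon_loss["loss_fold"], threshold=ts_fold)
                utr3, _ = metrics.utr3_abundance(
                    by_group, self.exon_lengths.loc[exp_idx], classes
                )

        recovered = {}
        if self.ground_truth:
            recovered = {
                "excess_loss_per_kb": {
                    "true": self.ground_truth.get("old_excess_loss_per_kb"),
                    "estimated": slope,
                },
            }
            if stall_est is not None:
                recovered["stalling_percent"] = {
                    "true": self.ground_truth.get("stalling_target_percent"),
                    "estimated": stall_est.mean_percent,
                }

        return TranscriptionalStressResults(
            model=self,
            expressed_genes=expressed,
            density_change=change,
            per_bin_pvalues=pvals,
            length_classes=classes,
            class_decline=class_decline,
            loss_slope_per_kb=slope,
            loss_slope_se=slope_se,
            stalling_estimate=stall_est,
            stalling_by_class=stall_by_class,
            gene_groups=groups,
            strand_bias_thirds=sb_thirds,
            strand_bias_by_class=sb_class,
            exon_loss=exon_loss,
            ts_high=ts_high,
            utr3_ratio=utr3,
            nascent_output_fold=float(fold),
            recovered_vs_truth=recovered,
        )


def per_bin_ttest(
    old_replicates: list[pd.DataFrame], adult_replicates: list[pd.DataFrame]
) -> pd.DataFrame:
    """Unpaired two-sided t-test per bin on replicate-level bin means.

    Each replicate contributes one value per bin (its cross-gene mean
    density); groups need >= 2 replicates. Returns raw p-values, the
    degrees of freedom, and Benjamini-Hochberg adjusted q-values.
    """
    from statsmodels.stats.multitest import multipletests

    if min(len(old_replicates), len(adult_replicates)) < 2:
        raise ValueError("need >= 2 replicates per group")
    old = np.vstack([m.mean(axis=0).to_numpy() for m in old_replicates])
    adult = np.vstack([m.mean(axis=0).to_numpy() for m in adult_replicates])
    t, p = stats.ttest_ind(old, adult, axis=0)
    dof = old.shape[0] + adult.shape[0] - 2
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"t": t, "p": p, "q_bh": q, "df": dof},
        index=old_replicates[0].columns,
    )


def config_hash(config: SimConfig, fit_kwargs: dict | None = None) -> str:
    """Provenance hash of a run configuration."""
    payload = {"config": config.to_dict(), "fit": fit_kwargs or {}}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
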