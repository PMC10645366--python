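"""qPCR validation arithmetic, pipeline orchestration and the run report.

The qPCR quantities follow the standard comparative-Ct scheme:
DeltaCt = Ct(target) - Ct(reference gene), DeltaDeltaCt = DeltaCt - mean
wild-type DeltaCt, fold change = 2^(-DeltaDeltaCt).  The pipeline runs
simulate -> differential expression -> feature enrichment -> APA (events,
motif windows, site-ratio comparison) -> trans-splicing and emits one
consolidated, deterministic report.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import apa as apa_mod
from . import diffexpr, feature_enrichment, trans_splicing
from ._stats import welch_t_p
from .core_io import (
    MAX_CT,
    CoverageTrack,
    load_annotation,
    load_coverage,
    read_counts,
    read_fasta,
    read_junctions,
)
from .synthetic_data import SimConfig, SimDataset, simulate_dataset

logger = logging.getLogger(__name__)

# significance annotation thresholds used in report tables
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    for cut, mark in STAR_LEVELS:
        if p < cut:
            return mark
    return ""


# ---------------------------------------------------------------------------
# qPCR arithmetic
# ---------------------------------------------------------------------------

def delta_ct(
    ct_table: pd.DataFrame, target: str, reference: str = "gapdh"
) -> pd.DataFrame:
    """Per-sample DeltaCt = Ct(target) - Ct(reference).

    Records with Ct >= 40 cycles are rejected with a diagnostic; a sample
    must carry both the target and the reference amplicon.
    """
    df = ct_table.copy()
    bad = df["ct"] >= MAX_CT
    if bad.any():
        for _, row in df[bad].iterrows():
            logger.warning("rejecting Ct %.2f >= %d cycles (%s/%s)",
                           row["ct"], int(MAX_CT), row["target"], row["sample"])
        df = df[~bad]
    wide = df.pivot_table(index="sample", columns="target", values="ct")
    for col in (target, reference):
        if col not in wide.columns or wide[col].isna().any():
            raise ValueError(f"missing Ct for {col!r} in some sample")
    out = (wide[target] - wide[reference]).rename("delta_ct").reset_index()
    out.insert(1, "target", target)
    return out


def relative_expression(
    delta_cts: pd.DataFrame,
    wt_samples: Sequence[str],
    groups: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """WT-normalized expression: DeltaDeltaCt and fold = 2^(-DeltaDeltaCt).

    ``delta_cts`` is the frame from :func:`delta_ct`.  Per-sample values
    are normalized to the mean wild-type DeltaCt.  When ``groups`` maps
    samples to condition labels, each non-WT group additionally gets a
    two-sided Welch t-test on replicate DeltaCts against the wild type.
    """
    wt = delta_cts[delta_cts["sample"].isin(set(wt_samples))]
    if wt.empty:
        raise ValueError("no wild-type samples found")
    wt_mean = wt["delta_ct"].mean()
    out = delta_cts.copy()
    out["delta_delta_ct"] = out["delta_ct"] - wt_mean
    out["fold"] = 2.0 ** (-out["delta_delta_ct"])
    tests = []
    if groups is not None:
        out["group"] = out["sample"].map(dict(groups))
        wt_vals = wt["delta_ct"].values
        for grp, sub in out.groupby("group"):
            if sub["sample"].isin(set(wt_samples)).all():
                continue
            if len(sub) < 2 or len(wt_vals) < 2:
                continue
            p = welch_t_p(sub["delta_ct"].values, wt_vals)
            tests.append({"target": sub["target"].iloc[0], "group": grp,
                          "mean_fold": float(sub["fold"].mean()),
                          "p": p, "stars": stars(p)})
    return out, pd.DataFrame(tests, columns=["target", "group", "mean_fold",
                                             "p", "stars"])


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Thresholds and inputs for one pipeline run.

    Either ``simulate`` holds a :class:`SimConfig` or ``input_dir`` points
    at a dataset directory in the layout written by
    :func:`u1seq.synthetic_data.write_dataset`.
    """

    simulate: Optional[SimConfig] = None
    input_dir: Optional[str] = None
    outdir: Optional[str] = None
    fc_threshold: float = diffexpr.FC_THRESHOLD
    fdr_de: float = diffexpr.DE_FDR_THRESHOLD
    delta_pdui: float = apa_mod.DELTA_PDUI_THRESHOLD
    fdr_apa: float = apa_mod.APA_FDR_THRESHOLD
    window: int = apa_mod.U1_WINDOW
    motif: apa_mod.MotifConfig = field(default_factory=apa_mod.MotifConfig)
    reference: str = "WT"
    pdui_tolerance: float = 0.05  # truth-recovery tolerance in simulate mode

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulate / input_dir is required")
        for name in ("fc_threshold", "fdr_de", "delta_pdui", "fdr_apa", "window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _load_dataset(input_dir: str) -> SimDataset:
    genome = read_fasta(os.path.join(input_dir, "genome.fa"))
    models = load_annotation(
        os.path.join(input_dir, "annotation.gtf"),
        os.path.join(input_dir, "polya.bed"),
        genome=genome,
    )
    counts = read_counts(
        os.path.join(input_dir, "counts.tsv"), os.path.join(input_dir, "samples.tsv")
    )
    junctions = read_junctions(os.path.join(input_dir, "junctions.tsv"))
    coverage: dict[str, list[CoverageTrack]] = {}
    apa_models = [m for m in models if m.has_apa_sites]
    covdir = os.path.join(input_dir, "coverage")
    for sid in counts.samples.index:
        path = os.path.join(covdir, f"{sid}.bedGraph")
        coverage[sid] = load_coverage(
            path,
            [m.utr3 for m in apa_models],
            sample=sid,
            gene_ids=[m.gene_id for m in apa_models],
        )
    ds = SimDataset(
        config=None, genome=genome, models=models, counts=counts,
        coverage=coverage, junctions=junctions, truth=None,
    )
    return ds


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the consolidated report dict.

    In simulate mode the report additionally carries truth-vs-estimate
    recovery metrics.  The report is a plain JSON-serializable structure;
    with ``outdir`` set, stage tables are also written as TSV and the
    report as ``report.json``.
    """
    stage = "input"
    try:
        if config.simulate is not None:
            ds = simulate_dataset(config.simulate)
        else:
            ds = _load_dataset(config.input_dir)
        report: dict = {"seed": ds.config.seed if ds.config else None}
        models_by_id = {m.gene_id: m for m in ds.models}
        tables: dict[str, pd.DataFrame] = {}

        # ---------------- differential expression ----------------
        stage = "diffexpr"
        strains = [s for s in ds.counts.strains if s != config.reference]
        de_results = {}
        deg_down: dict[str, set] = {}
        deg_up: dict[str, set] = {}
        de_summary = {}
        for strain in strains:
            res = diffexpr.test_de(ds.counts, strain, reference=config.reference)
            sets = diffexpr.screen_degs(res, config.fc_threshold, config.fdr_de)
            de_results[strain] = diffexpr.add_calls(
                res, fc_threshold=config.fc_threshold, fdr_threshold=config.fdr_de
            )
            deg_down[strain], deg_up[strain] = sets["down"], sets["up"]
            n_tested = int(res["tested"].sum())
            de_summary[strain] = {
                "down": len(sets["down"]), "up": len(sets["up"]),
                "tested": n_tested,
                "ns": n_tested - len(sets["down"]) - len(sets["up"]),
            }
            tables[f"de_{strain}"] = de_results[strain]
        report["degs"] = de_summary
        report["deg_overlap"] = {
            direction: {
                "common": len(part["common"]),
                "unique": {s: len(v) for s, v in part["unique"].items()},
                "by_multiplicity": {
                    str(k): len(v) for k, v in sorted(part["by_multiplicity"].items())
                },
            }
            for direction, part in (
                ("down", diffexpr.overlap_sets(deg_down)),
                ("up", diffexpr.overlap_sets(deg_up)),
            )
        }

        # ---------------- feature enrichment ----------------
        stage = "feature_enrichment"
        strata = feature_enrichment.stratify_genes(ds.models)
        wt_cols = ds.counts.samples_for(config.reference)
        norm = diffexpr.normalized_counts(ds.counts)
        background = set(
            norm.index[norm[wt_cols].mean(axis=1) >= diffexpr.MIN_BASE_MEAN]
        )
        enrich_frames = []
        for strain in strains:
            rep = feature_enrichment.enrichment_report(
                {"down": deg_down[strain], "up": deg_up[strain]},
                background, strata,
            )
            rep.insert(0, "strain", strain)
            enrich_frames.append(rep)
        enrichment = pd.concat(enrich_frames, ignore_index=True)
        tables["enrichment"] = enrichment
        sig = enrichment[enrichment["fdr"] < 0.05]
        report["enrichment"] = {
            "n_background": len(background),
            "significant_bins": [
                f"{r.strain}:{r.direction}:{r.feature}:{r.bin}"
                for r in sig.itertuples()
            ],
        }

        # ---------------- APA ----------------
        stage = "apa"
        ests = []
        for sid, tracks in sorted(ds.coverage.items()):
            for t in tracks:
                ests.append(apa_mod.estimate_pdui(t))
        est_df = apa_mod.estimates_frame(ests)
        tables["pdui_estimates"] = est_df
        event_frames = []
        apa_summary = {}
        for strain in strains:
            ev = apa_mod.call_apa_events(
                est_df, ds.counts.samples, strain, reference=config.reference,
                delta_threshold=config.delta_pdui, fdr_threshold=config.fdr_apa,
            )
            ev["region_class"] = [
                apa_mod.classify_event_region(g, models_by_id.get(g))
                for g in ev["gene_id"]
            ]
            event_frames.append(ev)
            counts = ev["direction"].value_counts()
            apa_summary[strain] = {
                "distal": int(counts.get("distal", 0)),
                "proximal": int(counts.get("proximal", 0)),
                "ns": int(counts.get("ns", 0)),
            }
        events = (
            pd.concat(event_frames, ignore_index=True)
            if event_frames
            else pd.DataFrame(columns=["gene_id", "direction", "strain"])
        )
        tables["apa_events"] = events
        report["apa_events"] = apa_summary

        stage = "u1_windows"
        window_counts = {}
        wc_rows = []
        for m in ds.models:
            if not m.has_apa_sites:
                continue
            wc = apa_mod.window_site_counts(
                m.gene_id, ds.genome, m, window=config.window,
                motif_config=config.motif,
            )
            window_counts[m.gene_id] = wc
            wc_rows.append({"gene_id": m.gene_id,
                            "n_proximal_window": wc.n_proximal_window,
                            "n_distal_window": wc.n_distal_window})
        tables["u1_window_counts"] = pd.DataFrame(wc_rows)
        ratio_table = apa_mod.compare_site_ratios(events, window_counts)
        tables["site_ratios"] = ratio_table
        report["u1_site_ratios"] = {
            r.group: {
                "n_events": int(r.n_events),
                "ratio_smoothed": round(float(r.ratio_smoothed), 4),
                "wilcoxon_p": None if pd.isna(r.wilcoxon_p) else float(r.wilcoxon_p),
                "low_n": bool(r.low_n),
            }
            for r in ratio_table.itertuples()
        }

        # ---------------- trans-splicing ----------------
        stage = "trans_splicing"
        lib_sizes = ds.counts.samples["library_size"].to_dict()
        usage = trans_splicing.quantify_isoform_usage(ds.junctions, lib_sizes)
        tables["trans_usage"] = usage
        cmp_frames = [
            trans_splicing.compare_usage(usage, ds.counts.samples, strain,
                                         reference=config.reference)
            for strain in strains
        ]
        trans_cmp = pd.concat(cmp_frames, ignore_index=True)
        tables["trans_comparison"] = trans_cmp
        report["trans_splicing"] = {
            strain: {
                row.isoform: round(float(row.ratio), 4)
                for row in trans_cmp[trans_cmp["strain"] == strain].itertuples()
                if not row.flagged
            }
            for strain in strains
        }

        # ---------------- truth recovery (simulate mode) ----------------
        if ds.truth is not None:
            stage = "recovery"
            report["recovery"] = _recovery_metrics(
                ds, est_df, events, de_results, config
            )

        if config.outdir:
            stage = "write"
            os.makedirs(config.outdir, exist_ok=True)
            for name, df in tables.items():
                df.to_csv(os.path.join(config.outdir, f"{name}.tsv"),
                          sep="\t", index=isinstance(df.index, pd.Index)
                          and df.index.name is not None)
            with open(os.path.join(config.outdir, "report.json"), "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
                fh.write("\n")
        return report
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err


def _recovery_metrics(ds, est_df, events, de_results, config) -> dict:
    truth = ds.truth
    out: dict = {}

    # PDUI recovery over gene x sample pairs
    strain_of = ds.counts.samples["strain"]
    est = est_df.copy()
    est["strain"] = est["sample"].map(strain_of)
    merged = est.merge(truth.apa, on=["gene_id", "strain"])
    if len(merged):
        err = (merged["pdui"] - merged["true_pdui"]).abs()
        out["pdui_recovery"] = {
            "n_pairs": int(len(merged)),
            "fraction_within_tol": round(
                float((err <= config.pdui_tolerance).mean()), 4
            ),
            "median_abs_error": round(float(err.median()), 4),
        }

    # APA direction accuracy against the planted response class
    cls = truth.genes["apa_class"]
    shift_strains = set(ds.config.apa.shift_strains)
    ev = events[events["strain"].isin(shift_strains)]
    want = cls.map({"distal_shift": "distal", "proximal_shift": "proximal"})
    shifted = ev[ev["gene_id"].map(cls).isin(["distal_shift", "proximal_shift"])]
    nulls = ev[ev["gene_id"].map(cls) == "null"]
    out["apa_direction"] = {
        "n_shifted": int(len(shifted)),
        "correct_direction_rate": round(
            float(
                (shifted["direction"] == shifted["gene_id"].map(want)).mean()
            ), 4,
        ) if len(shifted) else None,
        "n_null": int(len(nulls)),
        "null_ns_rate": round(float((nulls["direction"] == "ns").mean()), 4)
        if len(nulls) else None,
    }

    # DE screen recovery of planted effects
    per_strain = {}
    for strain, res in de_results.items():
        lfc = truth.expression[strain]
        affected = lfc[lfc != 0]
        if affected.empty:
            continue
        res_aff = res.loc[affected.index]
        correct = np.sign(res_aff["log2fc"]) == np.sign(affected)
        called = res_aff["call"].isin(["down", "up"]) & (
            res_aff["call"].map({"down": -1.0, "up": 1.0}) == np.sign(affected)
        )
        per_strain[strain] = {
            "n_affected": int(len(affected)),
            "screen_recovery_rate": round(float(called.mean()), 4),
            "sign_agreement": round(float(correct.mean()), 4),
        }
    out["de_recovery"] = per_strain
    return out


def report_json(report: dict) -> str:
    """Canonical serialization used for determinism checks."""
    return json.dumps(report, indent=2, sort_keys=True)
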