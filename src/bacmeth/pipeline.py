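"""End-to-end analysis over a simulated dataset.

Chains the stages exactly as they would run on real evidence files: QV-filter
and assign the kinetic calls per condition, call bisulfite cytosines and
assign m5C occurrences, classify occurrences across the four baseline
conditions, extract the conserved-unmethylated (protected) GATC set, test its
promoter enrichment, count pairwise mark differences against the AMP-R-like
condition, split protected sites by their Dam-overexpression state, and scan
GATC density. Used by the command-line report, the test suite and the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import compare, context, density, smrt, wgbs
from .simulate import AMPR_CONDITION, BASELINE_CONDITIONS, SimulatedDataset

#: Pool the bipartite partner strings for reporting pooled mark differences.
PARTNER_POOLS = {"motif IIIa": "motif III", "motif IIIb": "motif III"}


@dataclass
class AnalysisResult:
    smrt_statuses: dict[str, pd.DataFrame]
    smrt_summary: pd.DataFrame
    wgbs_summary: pd.DataFrame
    classes: pd.DataFrame
    protected: pd.DataFrame  # conserved-unmethylated motif I sites
    located: pd.DataFrame
    enrichment: pd.DataFrame
    diff_total: int
    diff_per_motif: pd.Series
    diff_sites: pd.DataFrame
    n_rescued: int
    n_still_unmethylated: int
    density_scan: density.WindowScan
    density_regions_sd: pd.DataFrame


def analyze(
    ds: SimulatedDataset,
    min_qv: float = 30.0,
    min_cov: int = 25,
    min_frac: float = 0.90,
    promoter_bp: int = 200,
    density_k: float = 2.0,
) -> AnalysisResult:
    """Run the full downstream analysis on a simulated dataset."""
    occ = ds.smrt_occurrences
    statuses: dict[str, pd.DataFrame] = {}
    summaries = []
    for cond in ds.smrt_conditions:
        calls = smrt.filter_calls(ds.smrt_calls(cond), min_qv=min_qv)
        status, _off = smrt.assign_calls(occ, calls, condition=cond)
        statuses[cond] = status
        summaries.append(smrt.summarize(status))
    smrt_summary = pd.concat(summaries, ignore_index=True)

    wgbs_summaries = []
    for cond in ds.wgbs_conditions:
        counts = ds.wgbs_report(cond)
        called = wgbs.call_methylated(counts, min_cov=min_cov, min_frac=min_frac)
        _status, summary = wgbs.assign_m5c(
            ds.wgbs_occurrences, called, condition=cond
        )
        wgbs_summaries.append(summary)
    wgbs_summary = pd.concat(wgbs_summaries, ignore_index=True)

    baseline = {c: statuses[c] for c in BASELINE_CONDITIONS}
    classes = compare.classify_across(baseline)
    protected = compare.protected_sites(classes, motif="motif I")

    located = context.classify_location(occ, ds.genes, promoter_bp=promoter_bp)
    enrichment = context.enrichment_table(classes, located)

    ref = BASELINE_CONDITIONS[0]
    diff_total, diff_per_motif, diff_sites = compare.diff_pair(
        statuses[ref], statuses[AMPR_CONDITION], partner_pools=PARTNER_POOLS
    )

    rescued, still = compare.dam_rescue(protected, statuses["DAM+"])

    occ1 = occ[occ["motif"] == "motif I"]
    scan = density.window_counts(ds.genome, occ1)
    regions_sd = density.call_regions(scan, k=density_k, dispersion="sd")

    return AnalysisResult(
        smrt_statuses=statuses,
        smrt_summary=smrt_summary,
        wgbs_summary=wgbs_summary,
        classes=classes,
        protected=protected,
        located=located,
        enrichment=enrichment,
        diff_total=diff_total,
        diff_per_motif=diff_per_motif,
        diff_sites=diff_sites,
        n_rescued=len(rescued),
        n_still_unmethylated=len(still),
        density_scan=scan,
        density_regions_sd=regions_sd,
    )


def recovery_metrics(ds: SimulatedDataset, result: AnalysisResult) -> dict:
    """Precision/recall of the recovered protected set against planted truth."""
    key = ["motif", "contig", "methylated_position", "methylated_strand"]
    planted = set(map(tuple, ds.smrt_occurrences.loc[ds.protected_mask, key].values))
    recovered = set(map(tuple, result.protected[key].values))
    tp = len(planted & recovered)
    precision = tp / len(recovered) if recovered else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    return {
        "n_planted": len(planted),
        "n_recovered": len(recovered),
        "precision": precision,
        "recall": recall,
    }
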