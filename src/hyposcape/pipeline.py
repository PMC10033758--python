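"""End-to-end orchestration of the chronic-hypoxia analysis.

The pipeline mirrors the study design: score a panel of cell lines, carry
the most and least hypoxia-responsive lines forward as the HH and HL
groups, run differential expression and splicing per line, normalize paired
hypoxia/normoxia variant calls and summarize the mutational landscape, call
windowed copy number per pair, stratify a patient cohort and compare
alteration frequencies — then report every group comparison with means,
95% CIs and p-values in a single machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from .cnv import run_cnv, segments_to_frame
from .expression import (
    call_splicing,
    de_results_to_frame,
    deg_set_algebra,
    moderated_de_test,
    splicing_results_to_frame,
)
from .io import write_json, write_tsv
from .landscape import (
    records_to_frame,
    summarize_landscape,
    top_mutated_genes,
    write_maf,
)
from .scoring import calls_to_frame, score_cell_lines, score_cohort, scores_to_frame
from .stats import alteration_concordance, t_test_unpaired
from . import synthetic

logger = logging.getLogger("hyposcape")


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A global-null study: no planted effects anywhere."""
    params = dict(
        seed=seed,
        group_effect=1.0,
        de_fraction=0.0,
        splice_fraction=0.0,
        hypoxia_rate_per_mb={"HH": 0.0, "HL": 0.0},
        cnv_segments=(),
        true_ploidy=2,
        alteration_enrichment=1.0,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def _comparison_dict(cmp) -> dict:
    return {
        "groups": list(cmp.labels),
        "n": list(cmp.n),
        "means": [round(m, 10) for m in cmp.means],
        "ci95": [[round(v, 10) for v in ci] for ci in cmp.ci95],
        "t": round(cmp.t_statistic, 10) if np.isfinite(cmp.t_statistic) else None,
        "df": round(cmp.df, 10),
        "p_value": round(cmp.p_value, 12),
        "flavor": cmp.test_flavor,
    }


def _group_metric_comparison(per_pair: pd.DataFrame, metric: str):
    hh = per_pair.loc[per_pair["group"] == "HH", metric].to_numpy(dtype=float)
    hl = per_pair.loc[per_pair["group"] == "HL", metric].to_numpy(dtype=float)
    return t_test_unpaired(hh, hl, labels=("HH", "HL"))


def run_pipeline(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> dict:
    """Run every stage on a simulated study and return the summary report.

    When ``out_dir`` is given, per-stage TSV/MAF outputs, the summary JSON
    and a run log (seed, version, parameters) are written there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": int(config.seed),
        "parameters": {
            "exome_size_mb": config.exome_size_mb,
            "window_size_bp": config.window_size_bp,
            "n_transcripts": config.n_transcripts,
            "n_patients": config.n_patients,
        },
    }

    # --- 1. cell-line hypoxia scoring and group selection -------------
    logger.info("stage score: signature fold changes and hypoxia scores")
    fc_table, fc_truth = synthetic.simulate_signature_fc(config)
    line_scores = score_cell_lines(fc_table)
    k = config.n_lines_per_group
    ranked = [s.cell_line for s in line_scores]  # already sorted descending
    hh_lines, hl_lines = ranked[:k], ranked[-k:]
    groups: dict[str, str] = {**{l: "HH" for l in hh_lines}, **{l: "HL" for l in hl_lines}}
    summary["scores"] = {
        "ranking": ranked,
        "relative_scores": {s.cell_line: round(s.relative_score, 10) for s in line_scores},
        "hh_lines": hh_lines,
        "hl_lines": hl_lines,
        "n_hh_by_sign": sum(1 for s in line_scores if s.group == "HH"),
    }
    if out is not None:
        write_tsv(fc_table, out / "signature_fc.tsv")
        write_tsv(scores_to_frame(line_scores), out / "cell_line_scores.tsv")

    selected = hh_lines + hl_lines

    # --- 2. differential expression per line --------------------------
    logger.info("stage de: moderated differential expression per cell line")
    de_sets: dict[str, set] = {}
    de_counts: dict[str, int] = {}
    for idx, line in enumerate(selected):
        matrix, sheet, _truth = synthetic.simulate_expression_matrix(config, instance=idx)
        results = moderated_de_test(matrix, sheet)
        sig = {r.transcript.split("_", 1)[1] for r in results if r.significant}
        de_sets[line] = sig
        de_counts[line] = len(sig)
        if out is not None:
            write_tsv(de_results_to_frame(results), out / f"de_{line}.tsv")
    common_all, hh_specific, hl_specific = deg_set_algebra(de_sets, groups)
    summary["differential_expression"] = {
        "n_significant": de_counts,
        "n_common_all": len(common_all),
        "n_hh_specific": len(hh_specific),
        "n_hl_specific": len(hl_specific),
        "tc_count_comparison": _comparison_dict(
            t_test_unpaired(
                [de_counts[l] for l in hh_lines],
                [de_counts[l] for l in hl_lines],
                labels=("HH", "HL"),
            )
        )
        if min(len(hh_lines), len(hl_lines)) >= 2
        else None,
    }

    # --- 3. alternative splicing per line -----------------------------
    logger.info("stage splice: splicing index and event selection per cell line")
    splice_counts: dict[str, int] = {}
    cassette_fraction: dict[str, float] = {}
    for idx, line in enumerate(selected):
        psr, pmap, gene, sheet, events, _truth = synthetic.simulate_splicing_signals(
            config, instance=idx
        )
        results = call_splicing(psr, pmap, gene, sheet, events)
        reported = [r for r in results if r.significant and not r.excluded]
        splice_counts[line] = len(reported)
        cassette = sum(1 for r in reported if r.event == "cassette exon")
        cassette_fraction[line] = cassette / len(reported) if reported else 0.0
        if out is not None:
            write_tsv(splicing_results_to_frame(reported), out / f"splicing_{line}.tsv")
    summary["splicing"] = {
        "n_significant": splice_counts,
        "cassette_exon_fraction": {k: round(v, 6) for k, v in cassette_fraction.items()},
    }

    # --- 4. paired mutational landscape -------------------------------
    logger.info("stage maf-delta/landscape: hypoxia-only variants, TMB, spectra")
    mafs, manifest, maf_truth = synthetic.simulate_paired_mafs(
        config, lines_per_group={"HH": hh_lines, "HL": hl_lines}
    )
    summaries, retained = summarize_landscape(
        mafs, manifest, config.exome_size_mb, groups=groups
    )
    per_pair = pd.DataFrame(
        {
            "pair_id": [s.pair_id for s in summaries],
            "cell_line": [s.cell_line for s in summaries],
            "group": [s.group for s in summaries],
            "tmb": [s.tmb for s in summaries],
            "n_retained": [s.n_retained for s in summaries],
        }
    )
    pooled_class: dict[str, int] = {}
    pooled_snv: dict[str, int] = {}
    ti_n = tv_n = 0
    for s in summaries:
        for cls, c in s.class_counts.items():
            pooled_class[cls] = pooled_class.get(cls, 0) + c
        for cls, c in s.snv_class_counts.items():
            pooled_snv[cls] = pooled_snv.get(cls, 0) + c
    ti_n = pooled_snv.get("C>T", 0) + pooled_snv.get("T>C", 0)
    tv_n = sum(pooled_snv.values()) - ti_n
    n_snv = ti_n + tv_n
    top_genes = top_mutated_genes(retained, n=10)
    tmb_cmp = _group_metric_comparison(per_pair, "tmb")
    summary["mutational_landscape"] = {
        "tmb_per_pair": {
            r.pair_id: round(r.tmb, 10) for r in per_pair.itertuples(index=False)
        },
        "tmb_group_comparison": _comparison_dict(tmb_cmp),
        "class_counts_pooled": dict(
            sorted(pooled_class.items(), key=lambda kv: (-kv[1], kv[0]))
        ),
        "snv_class_counts_pooled": pooled_snv,
        "transition_pct": round(100.0 * ti_n / n_snv, 6) if n_snv else 0.0,
        "transversion_pct": round(100.0 * tv_n / n_snv, 6) if n_snv else 0.0,
        "top_mutated_genes": [
            {
                "gene": r.gene,
                "samples_mutated": int(r.samples_mutated),
                "pct_samples_mutated": round(float(r.pct_samples_mutated), 6),
                "total_variants": int(r.total_variants),
            }
            for r in top_genes.itertuples(index=False)
        ],
        "exome_size_mb": config.exome_size_mb,
    }
    if out is not None:
        write_tsv(manifest, out / "pairing_manifest.tsv")
        write_tsv(per_pair, out / "tmb_per_pair.tsv")
        maf_dir = out / "maf_private"
        maf_dir.mkdir(exist_ok=True)
        for pair_id, records in retained.items():
            write_maf(records, maf_dir / f"{pair_id}.maf")

    # --- 5. windowed CNV per pair --------------------------------------
    logger.info("stage cnv: windowed copy-number calling per pair")
    cnv_rows = []
    for idx, s in enumerate(summaries):
        case, control, _truth = synthetic.simulate_coverage(config, instance=idx)
        _ratios, called, cnv_summary = run_cnv(case, control)
        cnv_rows.append(
            {
                "pair_id": s.pair_id,
                "group": s.group,
                "selected_ploidy": cnv_summary.selected_ploidy,
                "cnv_windows": cnv_summary.cnv_windows,
                "cng_windows": cnv_summary.cng_windows,
                "cnl_windows": cnv_summary.cnl_windows,
                "retained_windows": cnv_summary.retained_windows,
            }
        )
        if out is not None and idx == 0:
            write_tsv(segments_to_frame(called), out / "cnv_segments_first_pair.tsv")
    cnv_df = pd.DataFrame(cnv_rows)
    ploidy_mode = int(cnv_df["selected_ploidy"].mode().iloc[0])
    summary["cnv"] = {
        "selected_ploidy_mode": ploidy_mode,
        "per_pair": {
            r.pair_id: {
                "cnv": int(r.cnv_windows),
                "cng": int(r.cng_windows),
                "cnl": int(r.cnl_windows),
            }
            for r in cnv_df.itertuples(index=False)
        },
        "cnv_group_comparison": _comparison_dict(
            _group_metric_comparison(cnv_df, "cnv_windows")
        ),
        "cng_group_comparison": _comparison_dict(
            _group_metric_comparison(cnv_df, "cng_windows")
        ),
        "cnl_group_comparison": _comparison_dict(
            _group_metric_comparison(cnv_df, "cnl_windows")
        ),
    }
    if out is not None:
        write_tsv(cnv_df, out / "cnv_per_pair.tsv")

    # --- 6. cohort stratification and concordance ----------------------
    logger.info("stage stratify: cohort scoring and alteration concordance")
    expression, alterations, _truth = synthetic.simulate_cohort(config)
    calls = score_cohort(expression)
    patient_groups = {c.patient: c.group for c in calls}
    gene_list = [
        g for g in top_genes["gene"].tolist() if g in alterations.columns
    ]
    n_hh = sum(1 for g in patient_groups.values() if g == "HH")
    concordance = None
    if gene_list and 0 < n_hh < len(patient_groups):
        conc = alteration_concordance(alterations, patient_groups, gene_list)
        concordance = {
            "genes": conc.genes,
            "concordant_count": conc.concordant_count,
            "total": conc.total,
            "freq_hh": {g: round(v, 6) for g, v in conc.freq_high.items()},
            "freq_hl": {g: round(v, 6) for g, v in conc.freq_low.items()},
        }
    summary["cohort"] = {
        "n_patients": len(calls),
        "n_hh": n_hh,
        "n_hl": len(patient_groups) - n_hh,
        "concordance": concordance,
    }
    if out is not None:
        write_tsv(calls_to_frame(calls), out / "cohort_calls.tsv")
        write_tsv(alterations, out / "cohort_alterations.tsv", index=True)

    # --- findings roll-up (at the study's significance thresholds) -----
    findings = []
    if any(v > 0 for v in de_counts.values()):
        findings.append("differential_expression")
    if any(v > 0 for v in splice_counts.values()):
        findings.append("splicing")
    if tmb_cmp.p_value <= 0.05:
        findings.append("tmb_group_difference")
    for key in ("cnv_group_comparison", "cng_group_comparison", "cnl_group_comparison"):
        if summary["cnv"][key]["p_value"] is not None and summary["cnv"][key]["p_value"] <= 0.05:
            findings.append(key)
    summary["significant_findings"] = findings

    if out is not None:
        write_json(summary, out / "summary.json")
        log_lines = [
            f"hyposcape {__version__}",
            f"seed {config.seed}",
            "config " + repr(dataclasses.asdict(config)),
        ]
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def _setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
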