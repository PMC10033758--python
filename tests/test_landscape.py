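"""MAF handling, paired subtraction, TMB, spectra and top-gene ranking."""

import numpy as np
import pandas as pd
import pytest

from hyposcape import synthetic
from hyposcape.config import SimulationConfig
from hyposcape.errors import DomainError, FormatError, PairingError
from hyposcape.landscape import (
    MafRecord,
    classify_snv,
    compute_tmb,
    read_maf,
    resolve_pairs,
    subtract_paired,
    summarize_landscape,
    summarize_records,
    top_mutated_genes,
    write_maf,
)


def snp(pos, ref="C", alt="T", gene="G1", sample="s"):
    return MafRecord(gene, "chrS", pos, pos, ref, alt, "Missense_Mutation", "SNP", sample)


class TestMafIO:
    def test_round_trip(self, tmp_path, small_config):
        mafs, _, _ = synthetic.simulate_paired_mafs(small_config)
        sample, records = next(iter(mafs.items()))
        path = tmp_path / "one.maf"
        write_maf(records, path)
        assert read_maf(path) == records

    def test_empty_body(self, tmp_path):
        path = tmp_path / "empty.maf"
        write_maf([], path)
        assert read_maf(path) == []

    def test_comment_lines_skipped(self, tmp_path):
        path = tmp_path / "c.maf"
        write_maf([snp(10)], path)
        path.write_text("#version 1\n" + path.read_text())
        assert len(read_maf(path)) == 1

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.maf"
        pd.DataFrame({"Hugo_Symbol": ["g"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="Chromosome"):
            read_maf(path)

    def test_invalid_record_reported_with_line(self, tmp_path):
        path = tmp_path / "bad_row.maf"
        frame = pd.DataFrame(
            [["g", "chr1", 5, 5, "A", "A", "Silent", "SNP", "s"]],
            columns=[
                "Hugo_Symbol", "Chromosome", "Start_Position", "End_Position",
                "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Classification",
                "Variant_Type", "Tumor_Sample_Barcode",
            ],
        )
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="line 2"):
            read_maf(path)


class TestSubtractPaired:
    def test_self_subtraction_empty(self):
        records = [snp(i) for i in range(5)]
        assert subtract_paired(records, records) == []

    def test_single_private_variant(self):
        shared = [snp(i) for i in range(5)]
        private = snp(99, sample="h")
        assert subtract_paired(shared + [private], shared) == [private]

    def test_matches_set_difference_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pool = [snp(int(p)) for p in rng.choice(5000, size=60, replace=False)]
            h = list(rng.choice(pool, size=40, replace=False))
            n = list(rng.choice(pool, size=40, replace=False))
            expected = sorted(
                {r.key for r in h} - {r.key for r in n}
            )
            got = [r.key for r in subtract_paired(h, n)]
            assert sorted(got) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        h = [snp(int(p)) for p in rng.choice(1000, 30, replace=False)]
        n = [snp(int(p)) for p in rng.choice(1000, 30, replace=False)]
        once = subtract_paired(h, n)
        assert subtract_paired(once, n) == once

    def test_partition_size_identity(self):
        rng = np.random.default_rng(2)
        h = [snp(int(p)) for p in rng.choice(500, 40, replace=False)]
        n = [snp(int(p)) for p in rng.choice(500, 40, replace=False)]
        private = subtract_paired(h, n)
        overlap = {r.key for r in h} & {r.key for r in n}
        assert len(private) + len(overlap) == len(h)

    def test_duplicates_collapsed_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            out = subtract_paired([snp(1), snp(1)], [])
        assert len(out) == 1


class TestComputeTmb:
    def test_empty(self):
        assert compute_tmb([], 57.7) == 0.0

    def test_unit_rate(self):
        assert compute_tmb([snp(i) for i in range(57)], 57.0) == pytest.approx(1.0)

    def test_bad_exome_size(self):
        with pytest.raises(DomainError):
            compute_tmb([], 0.0)

    def test_poisson_rate_recovery(self):
        cfg = SimulationConfig(seed=17, n_lines_per_group=3)
        mafs, manifest, truth = synthetic.simulate_paired_mafs(cfg)
        tmbs = [
            compute_tmb(
                subtract_paired(mafs[r.hypoxia_sample], mafs[r.normoxia_sample]),
                cfg.exome_size_mb,
            )
            for r in truth[truth["group"] == "HH"].itertuples(index=False)
        ]
        assert np.mean(tmbs) == pytest.approx(3.0, abs=0.3)


class TestClassifySnv:
    @pytest.mark.parametrize(
        "ref, alt, label, kind",
        [
            ("C", "T", "C>T", "transition"),
            ("G", "A", "C>T", "transition"),
            ("A", "C", "T>G", "transversion"),
            ("T", "C", "T>C", "transition"),
            ("G", "C", "C>G", "transversion"),
        ],
    )
    def test_folding(self, ref, alt, label, kind):
        assert classify_snv(ref, alt) == (label, kind)

    def test_exhaustive_complement_consistency(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                assert classify_snv(ref, alt) == classify_snv(comp[ref], comp[alt])

    def test_invalid(self):
        with pytest.raises(DomainError):
            classify_snv("A", "A")


class TestSummaries:
    def test_transition_pct_partition(self):
        records = [snp(1, "C", "T"), snp(2, "G", "A"), snp(3, "A", "C"), snp(4, "C", "G")]
        s = summarize_records(records, 10.0)
        assert s["transition_pct"] == pytest.approx(50.0)
        assert s["transition_pct"] + s["transversion_pct"] == pytest.approx(100.0)
        assert sum(s["class_counts"].values()) == len(records)

    def test_transition_bias_recovered(self, small_config):
        mafs, manifest, _ = synthetic.simulate_paired_mafs(small_config)
        summaries, _ = summarize_landscape(mafs, manifest, small_config.exome_size_mb)
        snv = {}
        for s in summaries:
            for k, v in s.snv_class_counts.items():
                snv[k] = snv.get(k, 0) + v
        total = sum(snv.values())
        ti = snv.get("C>T", 0) + snv.get("T>C", 0)
        assert 100 * ti / total == pytest.approx(70, abs=5)

    def test_frameshift_ins_ranks_first_with_default_mixture(self, small_config):
        mafs, manifest, _ = synthetic.simulate_paired_mafs(small_config)
        summaries, _ = summarize_landscape(mafs, manifest, small_config.exome_size_mb)
        pooled = {}
        for s in summaries:
            for k, v in s.class_counts.items():
                pooled[k] = pooled.get(k, 0) + v
        assert max(pooled, key=pooled.get) == "Frame_Shift_Ins"

    def test_empty_pair_is_valid(self):
        manifest = pd.DataFrame(
            [
                ("n1", "L", "normoxia", 1, 1),
                ("h1", "L", "hypoxia", 1, 1),
            ],
            columns=["sample_id", "cell_line", "condition", "biological_rep", "technical_rep"],
        )
        summaries, retained = summarize_landscape({"n1": [], "h1": []}, manifest, 57.7)
        assert summaries[0].tmb == 0.0
        assert summaries[0].n_retained == 0

    def test_unmatched_manifest_rejected(self):
        manifest = pd.DataFrame(
            [("n1", "L", "normoxia", 1, 1)],
            columns=["sample_id", "cell_line", "condition", "biological_rep", "technical_rep"],
        )
        with pytest.raises(PairingError):
            resolve_pairs(manifest)


class TestTopMutatedGenes:
    def test_gene_in_all_pairs_ranks_first(self):
        retained = {
            f"p{i}": [snp(i * 10, gene="EVERY"), snp(i * 10 + 1, gene=f"only{i}")]
            for i in range(4)
        }
        table = top_mutated_genes(retained, n=3)
        assert table.iloc[0]["gene"] == "EVERY"
        assert table.iloc[0]["pct_samples_mutated"] == pytest.approx(100.0)

    def test_tie_broken_by_total_count(self):
        retained = {
            "p1": [snp(1, gene="A"), snp(2, gene="A"), snp(3, gene="A"), snp(4, gene="B")],
            "p2": [snp(5, gene="A"), snp(6, gene="A"), snp(7, gene="B"), snp(8, gene="B")],
        }
        table = top_mutated_genes(retained, n=2)
        assert list(table["gene"]) == ["A", "B"]  # both in 2 samples; A has 5 vs 3

    def test_matches_brute_force_tally(self, small_config):
        mafs, manifest, _ = synthetic.simulate_paired_mafs(small_config)
        _, retained = summarize_landscape(mafs, manifest, small_config.exome_size_mb)
        table = top_mutated_genes(retained, n=10)
        # brute-force oracle
        samples = {}
        totals = {}
        for pid, recs in retained.items():
            for g in {r.hugo_symbol for r in recs}:
                samples[g] = samples.get(g, 0) + 1
            for r in recs:
                totals[r.hugo_symbol] = totals.get(r.hugo_symbol, 0) + 1
        expected = sorted(samples, key=lambda g: (-samples[g], -totals[g], g))[:10]
        assert list(table["gene"]) == expected
        for row in table.itertuples(index=False):
            assert row.samples_mutated == samples[row.gene]
            assert row.total_variants == totals[row.gene]
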