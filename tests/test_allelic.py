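"""Allele classification, majority vote, ratios and the dilution series."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from smmipseq.allelic import (
    AlleleCounts,
    DilutionSeries,
    SnpTarget,
    allele_of_read,
    allelic_ratio,
    dilution_ratio_of_ratios,
    majority_vote_counts,
    majority_vote_counts_sam,
    read_snp_table,
    rewrite_umi_to_header,
)
from smmipseq.panel import Panel, Probe
from smmipseq.readproc import ReadLayout
from tests.conftest import make_read_pair, random_seq


@pytest.fixture
def snp_setup(rng):
    """One transcript, one SNP at offset 150, two probes with disjoint arms."""
    seq = random_seq(rng, 320)
    tx = {"TX": seq}
    probes = []
    for g0, name in [(100, "pA"), (70, "pB")]:
        probes.append(
            Probe(
                name=name,
                extension_arm=seq[g0 - 20 : g0],
                ligation_arm=seq[g0 + 100 : g0 + 120],
                target_id="TX",
                target_start=g0,
                target_end=g0 + 100,
            )
        )
    panel = Panel(probes)
    ref = seq[150]
    alt = next(b for b in "ACGT" if b != ref)
    snp = SnpTarget("rs1", "TX", 150, ref, alt, ("pA", "pB"))
    return panel, tx, snp


def snp_read(panel, tx, snp, probe_name, allele, umi, read_length=76):
    probe = panel[probe_name]
    seq = tx[probe.target_id]
    if allele == "alt":
        seq = seq[: snp.offset] + snp.alt_allele + seq[snp.offset + 1 :]
    return make_read_pair(probe, {probe.target_id: seq}, umi, read_length)


class TestAlleleOfRead:
    def test_ref_and_alt(self, snp_setup):
        panel, tx, snp = snp_setup
        for pn in ("pA", "pB"):
            for allele in ("ref", "alt"):
                pair = snp_read(panel, tx, snp, pn, allele, "AAACCCGGG")
                assert allele_of_read(pair, snp, panel[pn]) == allele

    def test_sequencing_error_is_other(self, snp_setup):
        panel, tx, snp = snp_setup
        third = next(b for b in "ACGT" if b not in (snp.ref_allele, snp.alt_allele))
        seq = tx["TX"]
        mutated = {"TX": seq[:150] + third + seq[151:]}
        pair = make_read_pair(panel["pA"], mutated, "AAACCCGGG")
        assert allele_of_read(pair, snp, panel["pA"]) == "other"

    def test_snp_outside_gap_fill_rejected(self, snp_setup):
        panel, tx, snp = snp_setup
        bad = SnpTarget("rs2", "TX", 20, "A", "G")
        with pytest.raises(ValueError):
            allele_of_read(("A" * 76, "C" * 76), bad, panel["pA"])


def brute_force_votes(groups):
    """Per-group tally oracle: strict winner or tie."""
    out = Counter()
    for calls in groups:
        c = Counter(calls)
        top = c.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            out["tied"] += 1
        else:
            out[top[0][0]] += 1
    return out


class TestMajorityVote:
    def test_three_to_one_majority(self, snp_setup):
        panel, tx, snp = snp_setup
        reads = [snp_read(panel, tx, snp, "pA", "ref", "AAAAAAAAA")] * 3
        reads += [snp_read(panel, tx, snp, "pA", "alt", "AAAAAAAAA")]
        counts = majority_vote_counts(reads, panel, [snp])
        row = counts.table.set_index("probe").loc["pA"]
        assert (row["ref"], row["alt"], row["tied"]) == (1, 0, 0)

    def test_exact_tie_discarded(self, snp_setup):
        panel, tx, snp = snp_setup
        reads = [snp_read(panel, tx, snp, "pA", "ref", "AAAAAAAAA")] * 2
        reads += [snp_read(panel, tx, snp, "pA", "alt", "AAAAAAAAA")] * 2
        counts = majority_vote_counts(reads, panel, [snp])
        row = counts.table.set_index("probe").loc["pA"]
        assert (row["ref"], row["alt"], row["tied"]) == (0, 0, 1)

    def test_same_umi_different_probes_independent(self, snp_setup):
        panel, tx, snp = snp_setup
        umi = "GGGTTTAAA"
        reads = [snp_read(panel, tx, snp, "pA", "ref", umi)] * 2
        reads += [snp_read(panel, tx, snp, "pB", "alt", umi)] * 2
        counts = majority_vote_counts(reads, panel, [snp])
        t = counts.table.set_index("probe")
        assert t.loc["pA", "ref"] == 1 and t.loc["pB", "alt"] == 1

    def test_matches_brute_force_on_random_groups(self, snp_setup, rng):
        panel, tx, snp = snp_setup
        reads = []
        groups = []
        for g in range(60):
            umi = random_seq(rng, 9)
            pn = "pA" if rng.random() < 0.5 else "pB"
            calls = [("ref" if rng.random() < 0.6 else "alt") for _ in range(int(rng.integers(1, 6)))]
            groups.append((pn, calls))
            for c in calls:
                reads.append(snp_read(panel, tx, snp, pn, c, umi))
        counts = majority_vote_counts(reads, panel, [snp])
        for pn in ("pA", "pB"):
            expected = brute_force_votes([c for p, c in groups if p == pn])
            row = counts.table.set_index("probe").loc[pn]
            assert (row["ref"], row["alt"], row["tied"]) == (
                expected["ref"],
                expected["alt"],
                expected["tied"],
            )

    def test_molecule_conservation(self, snp_setup, rng):
        """Allele-class counts sum to the number of distinct (probe, UMI) groups."""
        panel, tx, snp = snp_setup
        reads, keys = [], set()
        for _ in range(200):
            umi = random_seq(rng, 9)
            pn = "pA" if rng.random() < 0.5 else "pB"
            keys.add((pn, umi))
            reads.append(snp_read(panel, tx, snp, pn, "ref" if rng.random() < 0.5 else "alt", umi))
        counts = majority_vote_counts(reads, panel, [snp])
        total = counts.table[["ref", "alt", "other", "tied"]].to_numpy().sum()
        assert total == len(keys)


class TestAllelicRatio:
    @staticmethod
    def _counts(ref, alt):
        return AlleleCounts(
            pd.DataFrame([{"snp": "rs1", "probe": "pA", "sample": "s", "ref": ref, "alt": alt, "other": 0, "tied": 0}])
        )

    def test_simple_fraction(self):
        ratio, (lo, hi) = allelic_ratio(self._counts(75, 25), "rs1", "s")
        assert ratio == 0.75
        assert lo < 0.75 < hi

    def test_zero_ref_one_sided(self):
        ratio, (lo, hi) = allelic_ratio(self._counts(0, 50), "rs1", "s")
        assert ratio == 0.0 and lo == 0.0 and hi < 0.1

    def test_no_informative_molecules(self):
        assert allelic_ratio(self._counts(0, 0), "rs1", "s") is None

    def test_interval_coverage(self, rng):
        """Clopper-Pearson interval covers the true fraction >= nominally."""
        true = 0.6
        hits = 0
        reps = 300
        for _ in range(reps):
            ref = rng.binomial(2000, true)
            _, (lo, hi) = allelic_ratio(self._counts(ref, 2000 - ref), "rs1", "s")
            hits += lo <= true <= hi
        assert hits / reps >= 0.93


class TestDilutionSeries:
    def test_ideal_series_exact_rate(self):
        ratios = pd.DataFrame([[0.8 * 0.75**k for k in range(6)]], index=["rs1"])
        table, geo = dilution_ratio_of_ratios(DilutionSeries([0.75**k for k in range(6)], ratios))
        assert geo == pytest.approx(0.75, abs=1e-12)
        assert np.allclose(table["ratio"].dropna(), 0.75)

    def test_missing_step_reported(self):
        vals = [0.8, np.nan, 0.45, 0.34]
        table, geo = dilution_ratio_of_ratios(DilutionSeries([1.0, 0.75, 0.56, 0.42], pd.DataFrame([vals], index=["rs1"])))
        assert (table["note"] == "missing").sum() == 2
        assert geo == pytest.approx(0.34 / 0.45)

    def test_fractions_must_decrease(self):
        with pytest.raises(ValueError):
            DilutionSeries([0.5, 0.75], pd.DataFrame([[0.5, 0.4]], index=["a"]))


class TestRewriteUmi:
    def _write(self, path, recs):
        with open(path, "w") as fh:
            for name, seq in recs:
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")

    def test_umi_moved_to_header(self, tmp_path, snp_setup):
        panel, tx, snp = snp_setup
        umi = "AAACCCGGG"
        s1, s2 = snp_read(panel, tx, snp, "pA", "ref", umi)
        self._write(tmp_path / "in1.fastq", [("r1", s1)])
        self._write(tmp_path / "in2.fastq", [("r1", s2)])
        n = rewrite_umi_to_header(
            (tmp_path / "in1.fastq", tmp_path / "in2.fastq"), (tmp_path / "o1.fastq", tmp_path / "o2.fastq")
        )
        assert n == 1
        lines = (tmp_path / "o2.fastq").read_text().splitlines()
        assert lines[0] == f"@r1:{umi}"
        assert lines[1] == s2[9:]
        assert len(lines[3]) == len(s2) - 9
        assert (tmp_path / "o1.fastq").read_text().splitlines()[0] == f"@r1:{umi}"

    def test_zero_umi_identity(self, tmp_path):
        recs = [("a", "ACGTACGT"), ("b", "GGGGCCCC")]
        for m in ("1", "2"):
            self._write(tmp_path / f"in{m}.fastq", recs)
        rewrite_umi_to_header(
            (tmp_path / "in1.fastq", tmp_path / "in2.fastq"),
            (tmp_path / "o1.fastq", tmp_path / "o2.fastq"),
            ReadLayout(umi_length=0),
        )
        assert (tmp_path / "o1.fastq").read_bytes() == (tmp_path / "in1.fastq").read_bytes()
        assert (tmp_path / "o2.fastq").read_bytes() == (tmp_path / "in2.fastq").read_bytes()


class TestSamBackend:
    def test_agrees_with_alignment_free_on_error_free_reads(self, snp_setup, tmp_path, rng):
        panel, tx, snp = snp_setup
        reads, sam_lines = [], []
        seq_ref = tx["TX"]
        sam_lines.append("@HD\tVN:1.6\tSO:coordinate")
        sam_lines.append(f"@SQ\tSN:TX\tLN:{len(seq_ref)}")
        for i in range(150):
            umi = random_seq(rng, 9)
            pn = "pA" if rng.random() < 0.5 else "pB"
            allele = "ref" if rng.random() < 0.7 else "alt"
            # reads long enough that mate 1 spans the whole gap-fill
            pair = snp_read(panel, tx, snp, pn, allele, umi, read_length=150)
            reads.append(pair)
            # mate 1 = lig arm (soft-clipped) + gap-fill (matched at target_start)
            probe = panel[pn]
            gap_len = len(pair[0]) - len(probe.ligation_arm)
            sam_lines.append(
                "\t".join(
                    [
                        f"r{i}:{umi}",
                        "0",
                        "TX",
                        str(probe.target_start + 1),
                        "60",
                        f"{len(probe.ligation_arm)}S{gap_len}M",
                        "*",
                        "0",
                        "0",
                        pair[0],
                        "I" * len(pair[0]),
                    ]
                )
            )
        sam_path = tmp_path / "reads.sam"
        sam_path.write_text("\n".join(sam_lines) + "\n")
        free = majority_vote_counts(reads, panel, [snp])
        sam = majority_vote_counts_sam(sam_path, panel, [snp])
        f = free.table.set_index("probe")[["ref", "alt"]]
        s = sam.table.set_index("probe")[["ref", "alt"]]
        assert f.to_dict() == s.to_dict()


def test_read_snp_table(tmp_path):
    path = tmp_path / "snps.tsv"
    path.write_text("snp_id\ttarget_id\toffset\tref\talt\tprobes\nrs1\tTX\t150\tA\tG\tpA,pB\n")
    snps = read_snp_table(path)
    assert snps[0].probes == ("pA", "pB") and snps[0].offset == 150
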