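"""Pair merging, demultiplexing and activity normalization."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from dirseq.design import build_constructs
from dirseq.errors import ConfigurationError, InputError
from dirseq.quant import (
    AnchorConfig,
    CountTable,
    demultiplex_count,
    merge_pairs,
    normalize_activity,
    revcomp,
)
from dirseq.simulate import SimulationTruth, fragment_sequence, simulate_counts, stream


def _pair(fragment: str) -> tuple[str, str]:
    return fragment, revcomp(fragment)


class TestMergePairs:
    def test_error_free_pair_merges_to_the_true_fragment(self, constructs):
        frag = fragment_sequence(constructs[3])
        merged, report = merge_pairs([frag], [revcomp(frag)])
        assert merged == [frag]
        assert report.merged == report.total == 1

    def test_irreconcilable_mates_are_discarded_and_tallied(self, constructs):
        f1 = fragment_sequence(constructs[0])
        f2 = fragment_sequence(constructs[17])  # different sub-library tag block
        rng = stream(0, "scramble")
        scrambled = "".join(rng.permutation(list(f2)))
        merged, report = merge_pairs([f1], [revcomp(scrambled)])
        assert merged == []
        assert report.merged == 0
        assert report.discarded_mismatch + report.discarded_ambiguous == 1

    def test_mate_count_mismatch_is_an_input_error(self):
        with pytest.raises(InputError, match="mate count"):
            merge_pairs(["ACGT" * 13], [])

    def test_merged_fraction_matches_closed_form_binomial(self, constructs):
        """1000 pairs at per-base error 0.005: P(merge) is the binomial
        probability of <= 2 visible mismatches over the 51-nt overlap, with
        per-position mismatch rate 2e(1-e) + (2/3)e^2."""
        frag = fragment_sequence(constructs[5])
        L = len(frag)
        e = 0.005
        rng = stream(42, "merge-mc")
        bases = np.array(list("ACGT"))

        def mutate(seq):
            arr = np.array(list(seq))
            mask = rng.random(L) < e
            arr[mask] = bases[(np.searchsorted(bases, arr[mask]) + rng.integers(1, 4, mask.sum())) % 4]
            return "".join(arr)

        r1 = [mutate(frag) for _ in range(1000)]
        r2 = [revcomp(mutate(frag)) for _ in range(1000)]
        _, report = merge_pairs(r1, r2, min_overlap=20, max_mismatch=2)
        p_mm = 2 * e * (1 - e) + (2 / 3) * e**2
        expected = stats.binom.cdf(2, L, p_mm)
        assert abs(report.merged / report.total - expected) < 0.02

    def test_partial_overlap_assembles_the_union(self):
        frag = "ACGTTGCAACGGATCGATCGTTACGCAT"  # 28 nt
        r1, r2 = frag[:24], revcomp(frag[4:])
        merged, report = merge_pairs([r1], [r2], min_overlap=15)
        assert merged == [frag]
        assert report.merged == 1


class TestDemultiplex:
    def _reads(self, constructs, ids):
        return [fragment_sequence(c) for c in constructs if c.construct_id in ids]

    def test_hand_written_reads_match_regex_oracle(self, constructs):
        """Ten reads with known identities, counted independently with a
        regular-expression scan over anchor + tag + barcode."""
        anchors = AnchorConfig()
        chosen = [constructs[i] for i in (0, 0, 0, 1, 1, 2, 7, 7, 20, 44)]
        reads = [fragment_sequence(c, anchors) for c in chosen]
        counts, unassigned = demultiplex_count(reads, constructs, anchors)
        oracle = {c.construct_id: 0 for c in constructs}
        pattern = re.compile(re.escape(anchors.upstream) + "([ACGT]{6})([ACGT]{2})")
        lookup = {(c.sublib_tag, c.barcode): c.construct_id for c in constructs}
        for read in reads:
            m = pattern.search(read)
            assert m is not None
            oracle[lookup[(m.group(1), m.group(2))]] += 1
        assert unassigned == 0
        assert counts.to_dict() == oracle

    def test_mutated_barcode_is_unassigned(self, constructs):
        anchors = AnchorConfig()
        read = fragment_sequence(constructs[0], anchors)
        pos = len(anchors.upstream) + anchors.tag_length  # first barcode base
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        mutated = read[:pos] + flip + read[pos + 1 :]
        # the mutated identity may collide with another construct's barcode;
        # pick a tag block where the neighbour does not exist
        counts, unassigned = demultiplex_count([mutated], constructs[:1], anchors)
        assert counts.sum() == 0 and unassigned == 1

    def test_anchor_tolerates_configured_mismatches(self, constructs):
        anchors = AnchorConfig()
        read = fragment_sequence(constructs[4], anchors)
        broken = "A" + read[1:] if read[0] != "A" else "C" + read[1:]
        counts, _ = demultiplex_count([broken], constructs, anchors, max_anchor_mismatch=1)
        assert counts[constructs[4].construct_id] == 1
        counts0, una0 = demultiplex_count([broken], constructs, anchors, max_anchor_mismatch=0)
        assert counts0.sum() == 0 and una0 == 1

    def test_empty_construct_table_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            demultiplex_count(["ACGT"], [])

    def test_conservation_assigned_plus_unassigned_equals_total(self, constructs):
        rng = stream(1, "demux-cons")
        bases = np.array(list("ACGT"))
        reads = [fragment_sequence(constructs[i % 45]) for i in range(200)]
        reads += ["".join(bases[rng.integers(0, 4, 51)]) for _ in range(50)]
        counts, unassigned = demultiplex_count(reads, constructs)
        assert counts.sum() + unassigned == 250

    def test_equivalence_with_brute_force_oracle_on_noisy_reads(self, constructs):
        """The vectorized demultiplexer and a naive per-read scan agree on
        2000 reads carrying random substitution errors."""
        anchors = AnchorConfig()
        rng = stream(2, "demux-oracle")
        bases = np.array(list("ACGT"))
        reads = []
        for i in range(2000):
            frag = np.array(list(fragment_sequence(constructs[i % 45], anchors)))
            mask = rng.random(frag.size) < 0.02
            frag[mask] = bases[(np.searchsorted(bases, frag[mask]) + rng.integers(1, 4, mask.sum())) % 4]
            reads.append("".join(frag))

        def oracle(read):
            best_pos, best_score, ties = None, 10**9, 0
            for p in range(len(read) - len(anchors.upstream) - 8 + 1):
                score = sum(a != b for a, b in zip(read[p : p + len(anchors.upstream)],
                                                   anchors.upstream))
                if score < best_score:
                    best_pos, best_score, ties = p, score, 1
                elif score == best_score:
                    ties += 1
            if best_score > 1 or ties > 1:
                return None
            start = best_pos + len(anchors.upstream)
            tag, bc = read[start : start + 6], read[start + 6 : start + 8]
            return {(c.sublib_tag, c.barcode): c.construct_id for c in constructs}.get((tag, bc))

        counts, unassigned = demultiplex_count(reads, constructs, anchors, max_anchor_mismatch=1)
        expected = {c.construct_id: 0 for c in constructs}
        n_un = 0
        for read in reads:
            cid = oracle(read)
            if cid is None:
                n_un += 1
            else:
                expected[cid] += 1
        assert counts.to_dict() == expected
        assert unassigned == n_un


def _toy_table():
    counts = pd.DataFrame(
        {"plasmid": [20, 20, 20], "L1_rep1": [10, 20, 40]},
        index=pd.Index(["ctrl", "c2", "c3"], name="construct_id"),
    )
    samples = pd.DataFrame(
        [
            {"sample": "plasmid", "cell_line": "", "replicate": 0, "material": "plasmid"},
            {"sample": "L1_rep1", "cell_line": "L1", "replicate": 1, "material": "cdna"},
        ]
    )
    return CountTable(counts=counts, samples=samples)


class TestNormalizeActivity:
    def test_toy_counts_give_activities_one_two_four(self):
        act = normalize_activity(_toy_table(), "ctrl", min_input_count=1)
        assert act.activity["L1_rep1"].tolist() == [1.0, 2.0, 4.0]

    def test_control_activity_is_exactly_one_in_every_sample(self, constructs):
        table = simulate_counts(constructs, SimulationTruth(seed=3, depth=50_000))
        act = normalize_activity(table, "negctrl")
        assert (act.activity.loc["negctrl"] == 1.0).all()

    def test_scaling_a_sample_leaves_activities_unchanged(self):
        base = _toy_table()
        act1 = normalize_activity(base, "ctrl", min_input_count=1)
        scaled = base.counts.copy()
        scaled["L1_rep1"] *= 7
        act2 = normalize_activity(CountTable(scaled, base.samples), "ctrl", min_input_count=1)
        pd.testing.assert_frame_equal(act1.activity, act2.activity)

    @given(st.integers(2, 1000), st.integers(2, 1000), st.integers(1, 11))
    def test_scale_invariance_property(self, a, b, k):
        base = _toy_table()
        base.counts.loc["c2", "L1_rep1"] = a
        base.counts.loc["c3", "plasmid"] = b
        act1 = normalize_activity(base, "ctrl", min_input_count=1)
        scaled = base.counts.copy()
        scaled["plasmid"] *= k
        act2 = normalize_activity(CountTable(scaled, base.samples), "ctrl", min_input_count=1)
        assert np.allclose(act1.activity, act2.activity)

    def test_low_input_constructs_are_flagged_and_masked(self):
        base = _toy_table()
        base.counts.loc["c3", "plasmid"] = 3
        act = normalize_activity(CountTable(base.counts, base.samples), "ctrl", min_input_count=10)
        assert act.flags["c3"] == "low_input"
        assert np.isnan(act.activity.loc["c3", "L1_rep1"])
        assert act.flags["c2"] == "ok"

    def test_missing_or_empty_control_is_fatal(self):
        base = _toy_table()
        with pytest.raises(InputError, match="absent"):
            normalize_activity(base, "nope")
        base.counts.loc["ctrl", "plasmid"] = 0
        with pytest.raises(InputError):
            normalize_activity(CountTable(base.counts, base.samples), "ctrl", min_input_count=0)

    def test_pseudocount_rescues_zero_plasmid_constructs(self):
        base = _toy_table()
        base.counts.loc["c3", "plasmid"] = 0
        act = normalize_activity(
            CountTable(base.counts, base.samples), "ctrl", pseudocount=1.0, min_input_count=0
        )
        assert np.isfinite(act.activity.loc["c3", "L1_rep1"])


class TestCountTable:
    def test_roundtrip_through_tsv(self, constructs, tmp_path):
        table = simulate_counts(constructs, SimulationTruth(seed=4, depth=5000))
        table.write(tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = CountTable.read(tmp_path / "c.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(table.counts, back.counts)

    def test_two_plasmid_columns_rejected(self):
        base = _toy_table()
        samples = base.samples.copy()
        samples.loc[1, "material"] = "plasmid"
        with pytest.raises(InputError, match="plasmid"):
            CountTable(base.counts, samples)
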