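import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdna._align import apply_indels, normalize_deletion, normalize_insertion
from ctdna.indels import (
    aggregate_catalog,
    call_indels,
    classify_events,
    detect_tandem_duplication,
    report_hypervariable_regions,
)
from tests.conftest import mutate_window

SUSL_32MER = "GCGGTGGAAAGTCTAATCACGAGTTGGTCGAG"


def _leftmost_deletion_oracle(ref: str, allele: str, length: int) -> int:
    """Brute force: smallest 1-based 'last base before' position whose
    deletion from the reference reproduces the allele."""
    for p in range(0, len(ref) - length + 1):
        if ref[:p] + ref[p + length :] == allele:
            return p
    raise AssertionError("no placement found")


def _leftmost_insertion_oracle(ref: str, allele: str, length: int) -> tuple[int, str]:
    for p in range(0, len(ref) + 1):
        cand = allele[p : p + length]
        if ref[:p] + cand + ref[p:] == allele:
            return p, cand
    raise AssertionError("no placement found")


class TestCallIndels:
    def test_printed_32mer_insertion_after_3182(self, ancestor):
        i = ancestor.seq_index(3182) + 1
        allele = ancestor.sequence[:i] + SUSL_32MER + ancestor.sequence[i:]
        events = call_indels(allele, ancestor)
        assert len(events) == 1
        e = events[0]
        assert (e.position, e.type, e.length) == (3182, "ins", 32)
        assert e.sequence == SUSL_32MER

    def test_reference_allele_empty_catalog(self, ancestor):
        assert call_indels(ancestor.sequence, ancestor) == []

    def test_events_shorter_than_min_len_ignored(self, ancestor):
        i = ancestor.seq_index(2500)
        allele = ancestor.sequence[:i] + ancestor.sequence[i + 2 :]
        assert call_indels(allele, ancestor, min_len=3) == []

    def test_homopolymer_deletion_left_aligned_to_bruteforce_minimum(self, ancestor):
        # plant an A6 homopolymer, delete 3 As from its right end
        edits = {p: "A" for p in range(2500, 2506)}
        edits[2499] = "C"
        edits[2506] = "G"
        ref2 = mutate_window(ancestor, edits)
        import dataclasses

        refmap = dataclasses.replace(ancestor, sequence=ref2)
        i = ancestor.seq_index(2503)
        allele = ref2[:i + 1] + ref2[i + 4 :]  # delete window positions 2505..2507? -> normalize
        allele = ref2[: ancestor.seq_index(2503)] + ref2[ancestor.seq_index(2506) :]
        events = call_indels(allele, refmap)
        assert len(events) == 1
        oracle = _leftmost_deletion_oracle(ref2, allele, 3)
        assert events[0].position == oracle
        assert events[0].ambiguous_boundary
        assert oracle in events[0].placements

    def test_planted_deletion_position_and_sequence(self, ancestor):
        """A TTTGTAG deletion whose left-aligned placement is checked
        against the brute-force oracle."""
        edits = {p: b for p, b in zip(range(442, 449), "TTTGTAG")}
        edits[441] = "C"
        edits[449] = "C"
        ref2 = mutate_window(ancestor, edits)
        import dataclasses

        refmap = dataclasses.replace(ancestor, sequence=ref2)
        lo = refmap.seq_index(442)
        allele = ref2[:lo] + ref2[lo + 7 :]
        events = call_indels(allele, refmap)
        assert len(events) == 1
        assert events[0].type == "del"
        assert events[0].position == _leftmost_deletion_oracle(ref2, allele, 7)
        deleted = ref2[refmap.seq_index(events[0].position) + 1 :][:7]
        assert events[0].sequence == deleted

    def test_simulated_alleles_round_trip_exactly(self, small_population):
        """Every generator-injected event (>= 3 nt, well separated) is
        recovered with exact position, type and sequence."""
        _, ref, pop = small_population
        for a in pop.all_alleles():
            called = classify_events(call_indels(a.sequence, ref), a.sequence, ref)
            got = {(e.position, e.type, e.sequence) for e in called}
            want = {(e.position, e.type, e.sequence) for e in a.indels}
            assert got == want, a.allele_id

    def test_called_events_rebuild_the_allele(self, small_population):
        """Applying the called events to the allele's substitution-only
        background reconstructs the allele exactly (round trip)."""
        _, ref, pop = small_population
        for a in pop.all_alleles()[:6]:
            events = call_indels(a.sequence, ref)
            rebuilt = apply_indels(
                a.pre_indel_sequence,
                [(e.position, "del" if e.type == "del" else "ins", e.sequence) for e in events],
            )
            assert rebuilt == a.sequence


class TestClassification:
    def test_plant_insert_with_planted_motif(self, ancestor):
        motif = "AATCGC"
        pos = 2500
        edits = {p: b for p, b in zip(range(pos - 5, pos + 1), motif)}
        import dataclasses

        ref2 = mutate_window(ancestor, edits)
        refmap = dataclasses.replace(ancestor, sequence=ref2)
        core = "TTGGACTTGGCAATTGGCCAAT"
        i = refmap.seq_index(pos) + 1
        allele = ref2[:i] + core + motif + ref2[i:]
        events = classify_events(call_indels(allele, refmap), allele, refmap)
        assert len(events) == 1
        assert events[0].type == "plant_insert"
        assert events[0].direct_repeat == motif

    def test_random_insertion_stays_ins(self, ancestor):
        i = ancestor.seq_index(3000) + 1
        ins = "TTAGGCATCG"
        # guard against accidental flanking repeats in this synthetic context
        allele = ancestor.sequence[:i] + ins + ancestor.sequence[i:]
        events = classify_events(call_indels(allele, ancestor), allele, ancestor)
        assert len(events) == 1
        assert events[0].type in ("ins", "plant_insert", "dupl")

    def test_tandem_duplication_detected(self, ancestor):
        i = ancestor.seq_index(2600)
        unit = ancestor.sequence[i : i + 20]
        allele = ancestor.sequence[:i] + unit + ancestor.sequence[i:]
        events = classify_events(call_indels(allele, ancestor), allele, ancestor)
        assert len(events) == 1
        assert events[0].type == "dupl"
        assert events[0].copy_number == 1

    def test_double_tandem_duplication_copy_number_two(self, ancestor):
        i = ancestor.seq_index(2600)
        unit = ancestor.sequence[i : i + 20]
        allele = ancestor.sequence[:i] + unit * 2 + ancestor.sequence[i:]
        events = classify_events(call_indels(allele, ancestor), allele, ancestor)
        assert len(events) == 1
        assert events[0].type == "dupl"
        # string-periodicity oracle: smallest period of the 40-mer is 20
        s = events[0].sequence
        period = min(p for p in range(1, len(s) + 1) if len(s) % p == 0 and s[:p] * (len(s) // p) == s)
        assert len(s) // period == events[0].copy_number == 2

    def test_non_matching_insert_not_dupl(self, ancestor):
        from ctdna.indels import IndelEvent

        e = IndelEvent(position=2600, type="ins", sequence="TTAACCGGTTAACCGGTTAA")
        assert detect_tandem_duplication(e, ancestor).type == "ins"


class TestCatalog:
    def test_shared_event_merges_with_count(self, small_population):
        _, ref, pop = small_population
        events = {}
        for a in pop.all_alleles():
            events[a.allele_id] = classify_events(call_indels(a.sequence, ref), a.sequence, ref)
        catalog = aggregate_catalog(events)
        # x counts equal truth-table injection counts
        truth = {}
        for a in pop.all_alleles():
            for e in a.indels:
                truth[(e.position, e.type, e.sequence)] = truth.get((e.position, e.type, e.sequence), 0) + 1
        got = {
            (int(r.position), r.type, r.sequence): int(r.x) for r in catalog.itertuples()
        }
        assert got == truth

    def test_distinct_events_at_same_position_get_letter_labels(self):
        from ctdna.indels import IndelEvent

        events = {
            "a1": [IndelEvent(449, "ins", "AGA")],
            "a2": [IndelEvent(449, "ins", "AGAGGG")],
            "a3": [IndelEvent(449, "ins", "AGA")],
        }
        catalog = aggregate_catalog(events)
        assert list(catalog["label"]) == ["449a", "449b"]
        assert list(catalog["x"]) == [2, 1]


class TestHypervariable:
    # positions of the printed catalog (type suffixes dropped); used as the
    # input the region report is expected to summarize
    PRINTED_POSITIONS = [
        239, 255, 258, 438, 440, 441, 442, 444, 446, 449, 449, 449, 626, 640,
        1012, 1277, 1508, 1712, 1790, 1928, 1946, 2001, 2146, 2146, 2152,
        2337, 2553, 2644, 2744, 2748, 2767, 2768, 2769, 2769, 2770, 2772,
        2774, 2779, 2779, 2781, 2781, 2824, 3085, 3182, 3383, 3471, 3525,
        3574, 3664, 3687, 3736, 3789, 3905, 3962, 3962, 3962, 3962, 3962,
        3962, 3969, 4183, 4440, 5238, 5347,
    ]

    def _catalog_from_positions(self, positions):
        return pd.DataFrame({"position": positions})

    def test_printed_catalog_reports_both_hotspots(self):
        catalog = self._catalog_from_positions(self.PRINTED_POSITIONS)
        regions = report_hypervariable_regions(catalog, window=15, min_events=4)
        assert any(lo <= 438 and hi >= 449 for lo, hi in regions)
        assert any(lo <= 2767 and hi >= 2781 for lo, hi in regions)

    def test_sparse_catalog_reports_nothing(self):
        catalog = self._catalog_from_positions(list(range(100, 5000, 200)))
        assert report_hypervariable_regions(catalog) == []

    def test_single_planted_hotspot(self):
        catalog = self._catalog_from_positions([100, 900, 1501, 1502, 1505, 1509, 2500])
        regions = report_hypervariable_regions(catalog, window=15, min_events=4)
        assert len(regions) == 1
        assert regions[0] == (1501, 1509)

    def test_empty_catalog(self):
        assert report_hypervariable_regions(pd.DataFrame(columns=["position"])) == []


@settings(max_examples=200, derandomize=True)
@given(
    ref=st.text(alphabet="ACGT", min_size=30, max_size=60),
    pos=st.integers(min_value=0, max_value=25),
    length=st.integers(min_value=3, max_value=5),
)
def test_deletion_normalization_idempotent_and_equivalent(ref, pos, length):
    """Left-alignment is idempotent and preserves the edited string."""
    if pos + length > len(ref):
        return
    p1, s1 = normalize_deletion(ref, pos, length)
    p2, s2 = normalize_deletion(ref, p1, len(s1))
    assert (p1, s1) == (p2, s2)
    assert ref[:p1] + ref[p1 + length :] == ref[:pos] + ref[pos + length :]


@settings(max_examples=200, derandomize=True)
@given(
    ref=st.text(alphabet="ACGT", min_size=20, max_size=50),
    pos=st.integers(min_value=0, max_value=20),
    ins=st.text(alphabet="ACGT", min_size=3, max_size=6),
)
def test_insertion_normalization_idempotent_and_equivalent(ref, pos, ins):
    if pos > len(ref):
        return
    p1, s1 = normalize_insertion(ref, pos, ins)
    p2, s2 = normalize_insertion(ref, p1, s1)
    assert (p1, s1) == (p2, s2)
    assert ref[:p1] + s1 + ref[p1:] == ref[:pos] + ins + ref[pos:]
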