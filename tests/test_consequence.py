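"""Frame, PTC, NMD and domain calls on the exemplar fixtures and random
transcripts, checked against an independent Biopython translation oracle."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from bsplice.consequence import (
    StructuralMismatchError,
    TranscriptModel,
    apply_event,
    apply_events,
    classify_consequence,
    domain_truncation,
    frame_status,
    nmd_predict,
    scan_orf,
)
from bsplice.splicing import SpliceEvent


def oracle_first_stop(seq: str, cds_start: int):
    """Independent ORF scan: Biopython translation up to the first stop."""
    coding = seq[cds_start:]
    coding = coding[: len(coding) - len(coding) % 3]
    prot = str(Seq(coding).translate())
    idx = prot.find("*")
    return None if idx == -1 else cds_start + 3 * idx


@pytest.fixture()
def klhl12_d10_11(toy):
    tr, _, ev = toy
    return apply_events(
        tr["KLHL12_t1"],
        [(ev["SE_KLHL12_e10"], False), (ev["SE_KLHL12_e11"], False)],
    )


class TestApplyEvent:
    def test_skipping_116nt_exon(self, toy):
        tr, _, ev = toy
        v = apply_event(tr["SEC24C_t1"], ev["SE_SEC24C_e11"], inclusion=False)
        assert v.delta_length == -116

    def test_inclusion_of_reference_structure_is_identity(self, toy):
        tr, _, ev = toy
        v = apply_event(tr["SEC24C_t1"], ev["SE_SEC24C_e11"], inclusion=True)
        assert v.delta_length == 0
        assert v.seq == tr["SEC24C_t1"].spliced_seq

    def test_joint_cassette_pair_skip(self, klhl12_d10_11):
        assert klhl12_d10_11.delta_length == -(99 + 187)

    def test_poison_exon_inclusion(self, toy):
        tr, _, ev = toy
        v = apply_event(tr["SEC24D_t1"], ev["SE_SEC24D_poison"], inclusion=True)
        assert v.delta_length == 296
        assert len(v.exons) == len(tr["SEC24D_t1"].exons) + 1

    def test_a3ss_short_form(self, toy):
        tr, _, ev = toy
        v = apply_event(tr["NERF2_t1"], ev["A3SS_NERF_e7"], inclusion=False)
        assert v.delta_length == -45

    def test_structural_mismatch_raises(self, toy):
        tr, _, ev = toy
        with pytest.raises(StructuralMismatchError):
            apply_event(tr["SEC24C_t1"], ev["SE_KLHL12_e10"], inclusion=False)

    def test_involution_on_fixture_events(self, toy):
        """Applying an event and then its complementary form restores the
        original spliced sequence."""
        tr, _, ev = toy
        cases = [
            ("SEC24C_t1", "SE_SEC24C_e11", False),
            ("SEC24D_t1", "SE_SEC24D_poison", True),
            ("KLHL12_t1", "SE_KLHL12_e10", False),
            ("SEC31A_t1", "SE_SEC31A_alt", True),
            ("PICALM_t1", "SE_PICALM_e17", False),
            ("NERF2_t1", "A3SS_NERF_e7", False),
        ]
        for tid, eid, flag in cases:
            v = apply_event(tr[tid], ev[eid], inclusion=flag)
            back = apply_event(v.as_model(), ev[eid], inclusion=not flag)
            assert back.seq == tr[tid].spliced_seq, (tid, eid)


class TestFrameStatus:
    @pytest.mark.parametrize(
        "delta,preserved",
        [(-116, False), (-99, True), (0, True), (-296, False), (296, False),
         (-187, False), (-286, False), (-141, True), (-114, True)],
    )
    def test_exemplar_lengths(self, delta, preserved):
        assert frame_status(delta) is preserved


class TestScanOrf:
    def test_reference_stop_matches_annotation(self, toy):
        tr, _, _ = toy
        for t in tr.values():
            assert scan_orf(t.spliced_seq, t.cds_start) == t.cds_end - 3

    def test_no_stop_returns_none(self):
        assert scan_orf("ATGCCCACCGCA", 0) is None

    def test_destroyed_start_returns_none(self):
        assert scan_orf("ATGTAA", None) is None

    def test_matches_translation_oracle_on_random_transcripts(self):
        """500 random transcripts x random cassette events: the first
        in-frame stop agrees with a Biopython translation oracle, and frame
        status agrees with the sequence length difference mod 3."""
        rng = np.random.default_rng(99)
        bases = np.array(list("ACGT"))
        for _ in range(500):
            n_exons = rng.integers(3, 7)
            lens = rng.integers(30, 200, size=n_exons)
            gaps = rng.integers(20, 80, size=n_exons)
            exons, pos = [], 0
            for ln, gap in zip(lens, gaps):
                exons.append((pos + gap, pos + gap + ln))
                pos += gap + ln
            locus = "".join(rng.choice(bases, size=pos + 50))
            t = TranscriptModel("t", "g", exons, int(rng.integers(0, 12)) * 3, 3,
                                locus)
            k = int(rng.integers(1, n_exons - 1))
            event = SpliceEvent(
                "e", "g", "SE",
                segments={"upstream": exons[k - 1], "cassette": exons[k],
                          "downstream": exons[k + 1]},
            )
            v = apply_event(t, event, inclusion=bool(rng.integers(2)))
            assert frame_status(v.delta_length) == (
                (len(v.seq) - len(t.spliced_seq)) % 3 == 0
            )
            got = scan_orf(v.seq, v.cds_start)
            if v.cds_start is None:  # start codon removed with the cassette
                assert got is None
            else:
                assert got == oracle_first_stop(v.seq, v.cds_start)


class TestNmdPredict:
    def _variant(self, exon_lens, seq_len=None):
        """Minimal variant with the given exon lengths."""
        pos, exons = 0, []
        for ln in exon_lens:
            exons.append((pos, pos + ln))
            pos += ln
        locus = "A" * pos
        t = TranscriptModel("t", "g", exons, 0, 3, locus)
        v = apply_event(
            t,
            SpliceEvent("e", "g", "SE", segments={
                "upstream": exons[0], "cassette": exons[1], "downstream": exons[2]}),
            inclusion=True,
        )
        return v

    def test_stop_in_last_exon_escapes(self):
        v = self._variant([100, 100, 200])
        nmd, in_last = nmd_predict(v, 250)
        assert (nmd, in_last) == (False, True)

    def test_stop_100nt_upstream_of_last_junction_triggers_nmd(self):
        v = self._variant([100, 100, 200])
        nmd, in_last = nmd_predict(v, 100)  # 100 nt upstream of junction at 200
        assert (nmd, in_last) == (True, False)

    def test_stop_10nt_upstream_is_below_threshold(self):
        v = self._variant([100, 100, 200])
        nmd, in_last = nmd_predict(v, 190)
        assert (nmd, in_last) == (False, False)

    def test_single_exon_variant_escapes_by_definition(self):
        pos = 300
        t = TranscriptModel("t", "g", [(0, pos)], 0, 3, "A" * pos)
        v = apply_event(
            t,
            SpliceEvent("e", "g", "RI", segments={"intron": (100, 150)}),
            inclusion=True,
        )
        assert nmd_predict(v, 50) == (False, True)

    def test_monotone_in_ptc_position(self):
        """Moving a PTC upstream never flips NMD from True to False."""
        v = self._variant([100, 100, 200])
        states = [nmd_predict(v, p)[0] for p in range(0, 198, 3)]
        # once True going upstream, stays True: states must be non-increasing
        assert all(a >= b for a, b in zip(states, states[1:]))


class TestDomainTruncation:
    def test_reference_isoform_loses_nothing(self, toy):
        tr, domains, ev = toy
        v = apply_event(tr["KLHL12_t1"], ev["SE_KLHL12_e10"], inclusion=True)
        dd = domains[domains["transcript_id"] == "KLHL12_t1"]
        assert domain_truncation(v, dd) == ([], [])

    def test_klhl12_pair_skip_loses_three_of_six_repeats(self, toy, klhl12_d10_11):
        _, domains, _ = toy
        dd = domains[domains["transcript_id"] == "KLHL12_t1"]
        lost, truncated = domain_truncation(klhl12_d10_11, dd)
        assert sorted(lost) == ["kelch_4", "kelch_5", "kelch_6"]
        assert truncated == []

    def test_stop_before_all_domains_loses_all(self, toy, klhl12_d10_11):
        _, domains, _ = toy
        dd = domains[domains["transcript_id"] == "KLHL12_t1"]
        lost, _ = domain_truncation(klhl12_d10_11, dd, stop_pos=0)
        assert len(lost) == 6

    def test_domain_outside_cds_rejected(self, toy, klhl12_d10_11):
        bad = pd.DataFrame(
            [{"transcript_id": "KLHL12_t1", "domain_id": "x", "start": 0, "end": 40}]
        )
        with pytest.raises(ValueError):
            domain_truncation(klhl12_d10_11, bad)


class TestClassifyConsequence:
    def test_sec24c_skip_is_frameshift_nmd(self, toy):
        tr, domains, ev = toy
        v = apply_event(tr["SEC24C_t1"], ev["SE_SEC24C_e11"], inclusion=False)
        c = classify_consequence(v, domains)
        assert c.category == "frameshift-NMD"
        assert c.nmd_predicted and not c.stop_in_last_exon

    def test_sec24d_poison_inclusion_is_frameshift_nmd(self, toy):
        tr, domains, ev = toy
        v = apply_event(tr["SEC24D_t1"], ev["SE_SEC24D_poison"], inclusion=True)
        c = classify_consequence(v, domains)
        assert c.category == "frameshift-NMD"

    def test_klhl12_pair_skip_escapes_via_last_exon(self, toy, klhl12_d10_11):
        _, domains, _ = toy
        c = classify_consequence(klhl12_d10_11, domains)
        assert c.category == "frameshift-escape-alt-terminus"
        assert c.stop_in_last_exon and not c.nmd_predicted
        assert len(c.lost_domains) == 3

    def test_picalm_variants_frame_preserving_and_distinct(self, toy):
        tr, domains, ev = toy
        v13 = apply_event(tr["PICALM_t1"], ev["SE_PICALM_e13"], inclusion=False)
        v17 = apply_event(tr["PICALM_t1"], ev["SE_PICALM_e17"], inclusion=False)
        c13 = classify_consequence(v13, domains)
        c17 = classify_consequence(v17, domains)
        assert c13.category == c17.category == "frame-preserving"
        # distinct retained C-terminal coding segments
        tail13 = v13.seq[v13.cds_start : c13.stop_pos]
        tail17 = v17.seq[v17.cds_start : c17.stop_pos]
        assert tail13 != tail17

    def test_sec31a_inclusion_rescued_by_alt_start(self, toy):
        tr, domains, ev = toy
        v = apply_event(tr["SEC31A_t1"], ev["SE_SEC31A_alt"], inclusion=True)
        c = classify_consequence(v, domains)
        assert c.alt_start  # low-confidence downstream-AUG call
        assert c.category == "frameshift-escape-alt-terminus"
        without = classify_consequence(v, domains, allow_alt_start=False)
        assert without.category == "no-ORF"

    def test_categories_exclusive_and_exhaustive_on_fixture_suite(self, toy):
        tr, domains, ev = toy
        cats = set()
        for eid, e in ev.items():
            t = next(t for t in tr.values() if t.gene_id == e.gene_id)
            ref_has = e.etype != "SE" or e.segments["cassette"] in t.exons
            v = apply_event(t, e, inclusion=not ref_has)
            c = classify_consequence(v, domains)
            assert c.category in {
                "frame-preserving",
                "frameshift-NMD",
                "frameshift-escape-alt-terminus",
                "no-ORF",
            }
            cats.add(c.category)
        assert {"frame-preserving", "frameshift-NMD",
                "frameshift-escape-alt-terminus"} <= cats
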