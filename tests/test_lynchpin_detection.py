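"""Pairwise aligner, site↔column mapping, and the 3-state lynchpin rule."""

import random
import re

import pytest

from ohnolynch.lynchpin_detection import (
    AlignParams,
    call_lynchpin,
    column_to_site,
    map_site_to_column,
    needleman_wunsch,
    scan_families,
)
from ohnolynch.tabular_io import DataError, Msa, PhosphositeRecord


def alignment_score(x: str, y: str, p: AlignParams) -> float:
    """Score an explicit alignment: matrix over residue columns, affine gap runs."""
    s = 0.0
    for a, b in zip(x, y):
        if a != "-" and b != "-":
            s += p.match if a == b else p.mismatch
    for row in (x, y):
        for run in re.findall("-+", row):
            s -= p.gap_open + len(run) * p.gap_extend
    return s


def brute_force_best(a: str, b: str, p: AlignParams) -> float:
    """Exhaustive enumeration over all global alignments (small inputs only)."""
    best = [-float("inf")]

    def rec(i, j, xa, xb):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], alignment_score(xa, xb, p))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, xa + a[i], xb + b[j])
        if i < len(a):
            rec(i + 1, j, xa + a[i], xb + "-")
        if j < len(b):
            rec(i, j + 1, xa + "-", xb + b[j])

    rec(0, 0, "", "")
    return best[0]


class TestNeedlemanWunsch:
    def test_identical_strings_align_gapless(self):
        aa, bb, score = needleman_wunsch("MKTA", "MKTA")
        assert aa == bb == "MKTA" and score == 4.0

    def test_single_substitution_column(self):
        p = AlignParams(match=1, mismatch=-1, gap_open=5, gap_extend=1)
        aa, bb, score = needleman_wunsch("A", "G", p)
        assert (aa, bb, score) == ("A", "G", -1.0)

    @pytest.mark.parametrize(
        "params",
        [
            AlignParams(match=2, mismatch=-1, gap_open=2.5, gap_extend=0.5),
            AlignParams(match=1, mismatch=-2, gap_open=0.0, gap_extend=1.0),
            AlignParams(match=3, mismatch=0, gap_open=4.0, gap_extend=0.25),
        ],
    )
    def test_matches_exhaustive_enumeration(self, params):
        rng = random.Random(17)
        for _ in range(50):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            aa, bb, score = needleman_wunsch(a, b, params)
            assert score == pytest.approx(brute_force_best(a, b, params), abs=1e-9)
            # the traceback alignment itself achieves the optimum
            assert alignment_score(aa, bb, params) == pytest.approx(score, abs=1e-9)
            assert aa.replace("-", "") == a and bb.replace("-", "") == b

    def test_deterministic_under_tie_break(self):
        p = AlignParams(tie_break=("left", "up", "diagonal"))
        r1 = needleman_wunsch("ACCA", "ACA", p)
        r2 = needleman_wunsch("ACCA", "ACA", p)
        assert r1 == r2

    def test_empty_sequence_rejected(self):
        with pytest.raises(DataError):
            needleman_wunsch("", "A")


class TestSiteColumnMapping:
    def test_hand_mapping_with_gap(self):
        msa = Msa({"x": "A-CD", "y": "AACD"})
        assert map_site_to_column(msa, "x", 2) == 3  # A(1), C(2) → column 3

    def test_gapless_row_is_identity(self):
        msa = Msa({"x": "ACD", "y": "ACD"})
        for pos in (1, 2, 3):
            assert map_site_to_column(msa, "x", pos) == pos

    def test_round_trip_on_random_alignments(self):
        rng = random.Random(9)
        for _ in range(30):
            row = "".join(rng.choice("AC-") for _ in range(20)) + "A"
            msa = Msa({"x": row, "y": "G" * len(row)})
            ungapped_len = len(row.replace("-", ""))
            for pos in range(1, ungapped_len + 1):
                col = map_site_to_column(msa, "x", pos)
                assert column_to_site(msa, "x", col) == pos

    def test_position_beyond_ungapped_length_rejected(self):
        msa = Msa({"x": "A-C", "y": "AAC"})
        with pytest.raises(DataError):
            map_site_to_column(msa, "x", 3)


def _family_msa(member_res="SSSS", out_res="S", truncate_outgroup=False):
    """4 members + 1 outgroup, site at ungapped position 3 of m1 (column 3)."""
    rows = {}
    for i, r in enumerate(member_res, start=1):
        rows[f"m{i}"] = f"AA{r}AA"
    out_row = f"AA{out_res}AA"
    if truncate_outgroup:
        out_row = "AA---"  # trailing gap run covering the site column
    rows["og1"] = out_row
    return Msa(rows)


class TestCallLynchpin:
    def test_all_members_and_outgroup_serine_is_lynchpin(self):
        call = call_lynchpin(
            _family_msa(), {"m1", "m2", "m3", "m4"}, {"og1"}, ("m1", 3)
        )
        assert call.status == "lynchpin"

    def test_threonine_interchange_still_lynchpin(self):
        call = call_lynchpin(
            _family_msa("STST", "T"), {"m1", "m2", "m3", "m4"}, {"og1"}, ("m1", 3)
        )
        assert call.status == "lynchpin"

    def test_one_divergent_member_is_divergent(self):
        call = call_lynchpin(
            _family_msa("SSAS"), {"m1", "m2", "m3", "m4"}, {"og1"}, ("m1", 3)
        )
        assert call.status == "divergent"

    def test_non_st_outgroup_is_divergent(self):
        call = call_lynchpin(
            _family_msa("SSSS", "G"), {"m1", "m2", "m3", "m4"}, {"og1"}, ("m1", 3)
        )
        assert call.status == "divergent"

    def test_truncated_outgroup_is_unassignable(self):
        call = call_lynchpin(
            _family_msa(truncate_outgroup=True),
            {"m1", "m2", "m3", "m4"},
            {"og1"},
            ("m1", 3),
        )
        assert call.status == "unassignable"
        assert call.outgroup_residues["og1"] == "no-coverage"

    def test_internal_gap_counts_as_divergent_not_missing(self):
        msa = Msa({"m1": "AASAA", "m2": "AA-AA", "og1": "AASAA"})
        call = call_lynchpin(msa, {"m1", "m2"}, {"og1"}, ("m1", 3))
        assert call.status == "divergent"

    def test_second_outgroup_rescues_unassignable_but_never_flips_a_verdict(self):
        # monotone-in-evidence: adding an outgroup row can resolve unassignable,
        # but a lynchpin/divergent verdict never flips to the other one
        rng = random.Random(21)
        for _ in range(40):
            res = "".join(rng.choice("SAT") for _ in range(3))
            out1 = rng.choice(["S", "A", "T"])
            rows = {f"m{i+1}": f"AA{r}AA" for i, r in enumerate(res)}
            rows["og1"] = "AA---" if rng.random() < 0.4 else f"AA{out1}AA"
            base = call_lynchpin(
                Msa(rows), set(rows) - {"og1"}, {"og1"}, ("m1", 3)
            )
            rows2 = dict(rows)
            rows2["og2"] = f"AA{rng.choice('SAT')}AA"
            extended = call_lynchpin(
                Msa(rows2), set(rows) - {"og1"}, {"og1", "og2"}, ("m1", 3)
            )
            if base.status == "lynchpin":
                assert extended.status == "lynchpin"
            if base.status == "divergent":
                assert extended.status in ("divergent", "lynchpin")

    def test_require_all_outgroups_flag(self):
        rows = {"m1": "AASAA", "m2": "AASAA", "og1": "AASAA", "og2": "AAGAA"}
        msa = Msa(rows)
        members, outs = {"m1", "m2"}, {"og1", "og2"}
        assert call_lynchpin(msa, members, outs, ("m1", 3)).status == "lynchpin"
        strict = call_lynchpin(
            msa, members, outs, ("m1", 3), require_all_outgroups=True
        )
        assert strict.status == "divergent"

    def test_row_order_invariance(self):
        rows = {"m2": "AASAA", "m1": "AASAA", "og1": "AATAA"}
        a = call_lynchpin(Msa(rows), {"m1", "m2"}, {"og1"}, ("m1", 3))
        b = call_lynchpin(
            Msa(dict(reversed(rows.items()))), {"m2", "m1"}, {"og1"}, ("m1", 3)
        )
        assert a == b

    def test_precondition_violations_are_hard_errors(self):
        msa = _family_msa()
        with pytest.raises(DataError):
            call_lynchpin(msa, {"m1"}, {"og1"}, ("m1", 3))       # < 2 members
        with pytest.raises(DataError):
            call_lynchpin(msa, {"m1", "m2"}, set(), ("m1", 3))   # no outgroup
        with pytest.raises(DataError):
            call_lynchpin(msa, {"m1", "m2"}, {"og1"}, ("og1", 3))  # site not a member


class TestScanFamilies:
    def test_single_lynchpin_summary(self):
        alignments = {"f1": _family_msa()}
        roles = {"f1": {f"m{i}": "member" for i in range(1, 5)} | {"og1": "outgroup"}}
        sites = [PhosphositeRecord("m1", 3, "S", "gold")]
        calls, summary = scan_families(alignments, sites, roles)
        assert (
            summary.n_sites_evaluated,
            summary.n_lynchpins,
            summary.n_families_with_lynchpin,
            summary.n_unassignable,
        ) == (1, 1, 1, 0)

    def test_site_without_alignment_recorded_not_raised(self):
        calls, summary = scan_families(
            {}, [PhosphositeRecord("PX", 3, "S", "gold")], {}
        )
        assert calls[0].status == "unassignable"
        assert calls[0].reason == "no-alignment"

    def test_protein_in_two_alignments_is_hard_error(self):
        alignments = {"f1": _family_msa(), "f2": _family_msa()}
        roles = {
            "f1": {"m1": "member", "m2": "member", "og1": "outgroup"},
            "f2": {"m1": "member", "m3": "member", "og1": "outgroup"},
        }
        with pytest.raises(DataError):
            scan_families(alignments, [PhosphositeRecord("m1", 3, "S", "gold")], roles)

    def test_planted_classes_recovered_exactly(self, small_bundle):
        b = small_bundle
        calls, _ = scan_families(b.alignments, b.sites, b.roles)
        truth = {
            (s.protein_acc, s.position): s.status for s in b.truth.lynchpin_sites
        }
        assert len(calls) == len(truth)
        assert all(truth[c.reference_site] == c.status for c in calls)
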