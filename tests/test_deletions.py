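"""Microhomology arithmetic, staggered breakpoint assignment, deletion profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import amplijoin as aj
from _oracles import mh_by_enumeration
from amplijoin.deletions import (
    DeletionRecord,
    assign_breakpoints,
    deletion_profile,
    microhomology_length,
    records_from_calls,
)
from amplijoin.locus import ParameterError


class TestMicrohomologyLength:
    @pytest.mark.parametrize(
        "seq,interval,expected",
        [
            ("AACCGGTT", (2, 4), 0),  # no flanking identity
            ("ATCACACAGT", (3, 5), 4),  # 5 equivalent placements
            ("AAAAAA", (1, 3), 4),  # homopolymer: every placement equivalent
            ("AAAAAA", (2, 4), 4),
        ],
    )
    def test_known_cases(self, seq, interval, expected):
        assert microhomology_length(seq, interval) == expected
        assert mh_by_enumeration(seq, *interval) == expected

    def test_empty_interval_rejected(self):
        with pytest.raises(ParameterError):
            microhomology_length("ACGTACGT", (3, 3))

    @given(st.data())
    @settings(max_examples=200, derandomize=True)
    def test_equals_placement_enumeration_oracle(self, data):
        # mixture of unconstrained random sequences, homopolymer stretches and
        # planted direct repeats
        rng_seq = data.draw(
            st.one_of(
                st.text(alphabet="ACGT", min_size=6, max_size=30),
                st.text(alphabet="AC", min_size=6, max_size=20),
                st.builds(
                    lambda pre, rep, mid, post: pre + rep + mid + rep + post,
                    st.text(alphabet="ACGT", min_size=1, max_size=6),
                    st.text(alphabet="ACGT", min_size=1, max_size=4),
                    st.text(alphabet="ACGT", min_size=0, max_size=6),
                    st.text(alphabet="ACGT", min_size=1, max_size=6),
                ),
            )
        )
        i = data.draw(st.integers(min_value=1, max_value=len(rng_seq) - 1))
        j = data.draw(st.integers(min_value=i + 1, max_value=len(rng_seq)))
        assert microhomology_length(rng_seq, (i, j)) == mh_by_enumeration(rng_seq, i, j)

    def test_placement_independence(self):
        # every equivalent placement of the same product reports the same MH
        seq = "ATCACACAGT"
        product = seq[:3] + seq[5:]
        ks = {
            microhomology_length(seq, (p, p + 2))
            for p in range(1, len(seq) - 1)
            if seq[:p] + seq[p + 2 :] == product
        }
        assert ks == {4}


def _call(junction, read, **kw):
    from amplijoin.align import align_read
    from amplijoin.classify import classify_junction

    return classify_junction(align_read(read, junction), kw.get("read_id", "r0"))


class TestAssignBreakpoints:
    def test_plain_deletion_passes_through_unchanged(self, junction):
        seq, J = junction.sequence, junction.junction
        read = seq[: J - 3] + seq[J + 4 :]
        rec = assign_breakpoints(_call(junction, read), junction)
        assert not rec.fillin_adjusted
        assert rec.deletion_size == 7
        assert rec.mh_length == microhomology_length(seq, (J - 3, J + 4))

    @pytest.mark.parametrize("face", ["left", "right"])
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_staggered_product_recovers_net_size(self, junction, face, n):
        seq, J = junction.sequence, junction.junction
        d_true, t = 6, 6 + n
        if face == "left":
            read = seq[:J] + junction.fillin_left(n) + seq[J + t :]
        else:
            read = seq[: J - t] + junction.fillin_right(n) + seq[J:]
        rec = assign_breakpoints(_call(junction, read), junction)
        assert rec is not None
        assert rec.deletion_size == d_true
        if rec.fillin_adjusted:
            # smallest-shift precedence may legitimately pick n' < n when the
            # products coincide; the chosen explanation must reproduce the read
            n2, face2 = rec.overhang, rec.fillin_face
            fill = (
                junction.fillin_left(n2) if face2 == "left" else junction.fillin_right(n2)
            )
            t2 = d_true + n2
            expected = (
                seq[:J] + fill + seq[J + t2 :]
                if face2 == "left"
                else seq[: J - t2] + fill + seq[J:]
            )
            assert read == expected

    def test_unexplained_insert_stays_complex_and_excluded(self, junction):
        seq, J = junction.sequence, junction.junction
        # 5-nt insert adjacent to a 9-nt deletion, built so no base can be
        # absorbed as a match against either edge of the deleted segment and
        # so it matches no fill-in prediction (length > 2 * max_overhang - 1)
        ins = "".join(
            next(c for c in "ACGT" if c != seq[J + k] and c != seq[J + 4 + k])
            for k in range(5)
        )
        read = seq[:J] + ins + seq[J + 9 :]
        call = _call(junction, read)
        assert call.category == aj.COMPLEX_INDEL
        assert assign_breakpoints(call, junction) is None

    def test_simulated_staggered_fixture_matches_ground_truth(self, junction):
        cfg = aj.SimConfig(
            n_reads=300,
            seed=9,
            category_mix=(0, 0, 1, 0),
            p_staggered_deletion=1.0,
            substitution_error_rate=0,
        )
        reads, truth = aj.simulate_reads(junction, cfg)
        calls = aj.classify_all(reads, junction)
        recs = {r.read_id: r for r in records_from_calls(calls, junction)}
        assert len(recs) == len(truth)
        for _, row in truth.iterrows():
            rec = recs[row["read_id"]]
            assert rec.deletion_size == row["del_size"]
            if rec.fillin_adjusted and rec.overhang == max(
                row["overhang_left"], row["overhang_right"]
            ):
                assert rec.mh_length == row["mh_length"]

    def test_non_deletion_categories_yield_none(self, junction):
        call = _call(junction, junction.sequence)
        assert assign_breakpoints(call, junction) is None


class TestDeletionProfile:
    def test_single_record(self):
        prof = deletion_profile([DeletionRecord("r", 2, 2, ((5, 7),), read_count=10)])
        assert prof["size"]["deletion_size"].tolist() == [-2]
        assert prof["size"]["frequency"].tolist() == [1.0]
        assert prof["mh_usage"].set_index("mh")["fraction"]["2"] == 1.0

    def test_two_sizes_arithmetic(self):
        recs = [
            DeletionRecord("a", 2, 2, ((5, 7),), read_count=6),
            DeletionRecord("b", 1, 0, ((5, 6),), read_count=4),
        ]
        prof = deletion_profile(recs)
        size = prof["size"].set_index("deletion_size")["frequency"]
        assert size[-2] == pytest.approx(0.6)
        assert size[-1] == pytest.approx(0.4)
        usage = prof["mh_usage"].set_index("mh")["fraction"]
        assert usage["0"] == pytest.approx(0.4)
        assert usage["2"] == pytest.approx(0.6)

    def test_normalization_invariants(self, junction, clean_calls):
        recs = records_from_calls(clean_calls, junction)
        prof = deletion_profile(recs)
        assert prof["size"]["frequency"].sum() == pytest.approx(1.0)
        assert prof["mh_usage"]["fraction"].sum() == pytest.approx(1.0)
        per_size = prof["size_mh"].groupby("deletion_size")["fraction"].sum()
        assert np.allclose(per_size, 1.0)

    def test_empty_profile_flagged(self):
        prof = deletion_profile([])
        assert prof["size"].attrs["empty"]
        assert len(prof["mh_usage"]) == 0

    def test_planted_mh_recovery_at_repeat_lengths(self, junction):
        cfg = aj.SimConfig(
            n_reads=1500,
            seed=31,
            category_mix=(0, 0, 1, 0),
            w_mh=1.0,
            substitution_error_rate=0,
        )
        reads, truth = aj.simulate_reads(junction, cfg)
        calls = aj.classify_all(reads, junction)
        recs = records_from_calls(calls, junction)
        usage = deletion_profile(recs)["mh_usage"].set_index("mh")["fraction"]
        # planted repeats have lengths 2, 3, 4 drawn uniformly
        for k in ("2", "3", "4+"):
            sigma = np.sqrt((1 / 3) * (2 / 3) / cfg.n_reads)
            assert abs(usage.get(k, 0.0) - 1 / 3) < 3 * sigma
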