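"""Consensus scoring core: distances, z-scores, ranking, and a naive oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpscreen import (
    BitFingerprint,
    DegenerateDistributionError,
    FingerprintParams,
    apply_cutoff,
    build_index,
    consensus_score,
    euclidean_distance,
    screen,
    zscore_normalize,
)
from fpscreen.consensus import ScreenRow
from fpscreen.worked_example import CONSENSUS_CUTOFF, WORKED_EXAMPLE

from conftest import THREE_KINDS, record


def _fp(bits, n_bits=512, kind="avalon"):
    return BitFingerprint(kind=kind, n_bits=n_bits, on_bits=frozenset(bits))


# ---------------------------------------------------------------------------
# Naive reference implementations: explicit loops over dense 0/1 vectors,
# kept deliberately independent of the library's sparse-set code paths.
# ---------------------------------------------------------------------------

def naive_euclidean(a: BitFingerprint, b: BitFingerprint) -> float:
    va = [1 if i in a.on_bits else 0 for i in range(a.n_bits)]
    vb = [1 if i in b.on_bits else 0 for i in range(b.n_bits)]
    total = 0
    for x, y in zip(va, vb):
        total += (x - y) ** 2
    return math.sqrt(total)


def naive_zscores(values):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    sd = math.sqrt(var)
    return [(v - mean) / sd for v in values]


def naive_screen(query_fps, index):
    """Loop-based re-implementation of the whole screen."""
    dists = {}
    norms = {}
    for params in index.params:
        kind = params.kind
        dists[kind] = [
            naive_euclidean(query_fps[kind], fp) for fp in index.fingerprints[kind]
        ]
        norms[kind] = naive_zscores(dists[kind])
    out = []
    for i, rec in enumerate(index.records):
        per_kind = [norms[k][i] for k in index.kinds]
        out.append((rec.id, {k: dists[k][i] for k in index.kinds},
                    {k: norms[k][i] for k in index.kinds},
                    sum(per_kind) / len(per_kind)))
    out.sort(key=lambda t: (t[3], t[0]))
    return out


class TestEuclideanDistance:
    def test_identical_is_zero(self):
        fp = _fp({1, 5, 9})
        assert euclidean_distance(fp, fp) == 0.0

    def test_two_differing_bits(self):
        assert euclidean_distance(_fp({1, 2}), _fp({1, 3})) == pytest.approx(
            math.sqrt(2), abs=0
        )

    def test_symmetry_and_kind_checks(self):
        a, b = _fp({1, 2, 3}), _fp({4, 5})
        assert euclidean_distance(a, b) == euclidean_distance(b, a)
        with pytest.raises(ValueError, match="kind"):
            euclidean_distance(a, _fp({1}, kind="ecfp"))
        with pytest.raises(ValueError, match="length"):
            euclidean_distance(a, _fp({1}, n_bits=256))

    @given(
        st.sets(st.integers(0, 511), max_size=80),
        st.sets(st.integers(0, 511), max_size=80),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_coordinatewise_oracle(self, A, B):
        a, b = _fp(A), _fp(B)
        d = euclidean_distance(a, b)
        assert d == naive_euclidean(a, b)  # bit-for-bit
        assert round(d * d) == pytest.approx(d * d, abs=1e-9)  # integer square


class TestZScore:
    def test_hand_computed_example(self):
        out = zscore_normalize([1, 2, 3])
        assert out == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-6)

    def test_centering_and_unit_spread(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 30, size=200)
        out = zscore_normalize(vals)
        assert abs(out.mean()) < 1e-9
        assert abs(out.std(ddof=0) - 1) < 1e-9

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            zscore_normalize([5, 5, 5])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            zscore_normalize([1.0])

    def test_sample_sd_option(self):
        out = zscore_normalize([1, 2, 3], ddof=1)
        assert out == pytest.approx([-1.0, 0.0, 1.0], abs=1e-12)


class TestConsensusScore:
    @pytest.mark.parametrize("row", WORKED_EXAMPLE, ids=lambda r: f"compound{r.compound_id}")
    def test_published_worked_example(self, row):
        """Averaging the printed per-kind z-scores recovers the printed consensus."""
        got = consensus_score(list(row.norms.values()))
        assert got == pytest.approx(row.consensus_printed, abs=0.002)

    def test_permutation_invariance(self):
        assert consensus_score([-1.128, -4.196, -2.434]) == consensus_score(
            [-2.434, -1.128, -4.196]
        )

    @given(st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_mean_of_equal_scores_is_the_score(self, x):
        assert consensus_score([x, x, x]) == pytest.approx(x, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_score([])


class TestCutoff:
    def _rows(self, values):
        return [
            ScreenRow(str(i), ("k",), {"k": 0.0}, {"k": v}, v)
            for i, v in enumerate(values)
        ]

    def test_published_five_survivors(self):
        """The five published consensus values all sit strictly below -2.5."""
        rows = self._rows([r.consensus_printed for r in WORKED_EXAMPLE])
        assert len(apply_cutoff(rows, CONSENSUS_CUTOFF)) == 5

    def test_strict_boundary(self):
        rows = self._rows([-2.5, -2.500000001, -2.499])
        kept = apply_cutoff(rows, -2.5)
        assert [r.consensus for r in kept] == [-2.500000001]


class TestScreen:
    def test_exact_copy_of_query_ranks_first(self, decoy_corpus, query_record, three_kind_params):
        lib = [record(s, f"dec{i}") for i, s in enumerate(decoy_corpus[:15])]
        lib.append(record(query_record.smiles_input, "planted_copy"))
        rows = screen(query_record, build_index(lib, three_kind_params))
        assert rows[0].compound_id == "planted_copy"
        assert all(rows[0].distances[k] == 0.0 for k in THREE_KINDS)

    def test_no_cutoff_returns_all_rows(self, standard_index, query_record):
        rows = screen(query_record, standard_index)
        assert len(rows) == standard_index.size

    def test_consensus_is_mean_of_norms(self, standard_index, query_record):
        for row in screen(query_record, standard_index):
            assert row.consensus == pytest.approx(
                sum(row.norms.values()) / len(row.norms), abs=1e-9
            )

    def test_monotone_in_distance_within_kind(self, standard_index, query_record):
        rows = screen(query_record, standard_index)
        for kind in THREE_KINDS:
            ordered = sorted(rows, key=lambda r: r.distances[kind])
            norms = [r.norms[kind] for r in ordered]
            assert norms == sorted(norms)

    def test_library_order_does_not_change_ranking(self, standard_fixture, three_kind_params, query_record):
        fwd = screen(query_record, build_index(standard_fixture, three_kind_params))
        rev = screen(query_record, build_index(standard_fixture[::-1], three_kind_params))
        assert [r.compound_id for r in fwd] == [r.compound_id for r in rev]
        # summation order changes at most the last ulp of the statistics
        assert [r.consensus for r in fwd] == pytest.approx(
            [r.consensus for r in rev], abs=1e-12
        )

    def test_squared_distances_are_integers(self, standard_index, query_record):
        for row in screen(query_record, standard_index):
            for d in row.distances.values():
                assert round(d * d) == pytest.approx(d * d, abs=1e-6)

    def test_zero_variance_kind_aborts(self, three_kind_params, query_record):
        # Two identical structures under distinct ids: every kind degenerate.
        lib = [record("CCO", "a"), record("OCC", "b")]
        with pytest.raises(DegenerateDistributionError, match="kind"):
            screen(query_record, build_index(lib, three_kind_params))


class TestOracleEquivalence:
    def test_naive_reference_reproduces_everything(self, three_kind_params, query_record):
        """Loop-based re-implementation agrees on a 50-molecule seeded library."""
        from fpscreen import SyntheticLibrarySpec, generate_library
        from fpscreen.fingerprints import fingerprint

        lib = generate_library(SyntheticLibrarySpec(seed=11, n_decoys=45, n_analogs=5))
        index = build_index(lib, three_kind_params)
        assert index.size == 50
        rows = screen(query_record, index)
        qfps = {p.kind: fingerprint(query_record, p) for p in index.params}
        expected = naive_screen(qfps, index)

        assert [r.compound_id for r in rows] == [e[0] for e in expected]
        for row, (cid, dists, norms, cons) in zip(rows, expected):
            for k in THREE_KINDS:
                assert row.distances[k] == dists[k]  # exact: same integer sqrt
                assert row.norms[k] == pytest.approx(norms[k], abs=1e-12)
            assert row.consensus == pytest.approx(cons, abs=1e-12)
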