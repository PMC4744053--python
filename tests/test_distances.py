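"""Distance models, the per-site counting oracle, and stratified summaries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motudelim.barcode_io import AlignedBarcode
from motudelim.distances import (
    SaturationError,
    distance_matrix,
    low_divergence_pairs,
    max_intraspecific,
    pair_distance,
    rank_summaries,
)
from motudelim.synthetic_data import SimConfig, SpeciesSpec, simulate_dataset

from conftest import make_dataset

BASES = "ACGT"


def oracle_distance(x: str, y: str, model: str) -> tuple[float, int]:
    """Independent per-site counting oracle (plain loop, no vectorization)."""
    ts = tv = n = 0
    for a, b in zip(x.upper(), y.upper()):
        if a not in BASES or b not in BASES:
            continue
        n += 1
        if a == b:
            continue
        if {a, b} in ({"A", "G"}, {"C", "T"}):
            ts += 1
        else:
            tv += 1
    p_val = (ts + tv) / n
    if model == "p":
        return p_val, n
    if model == "jc69":
        return -0.75 * math.log(1 - 4 * p_val / 3), n
    P, Q = ts / n, tv / n
    return -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q)), n


def _mutate(seq: list[str], i: int, kind: str) -> None:
    ts_partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv_partner = {"A": "C", "G": "T", "C": "A", "T": "G"}
    seq[i] = (ts_partner if kind == "ts" else tv_partner)[seq[i]]


class TestPairDistance:
    def test_identical_sequences_zero_under_all_models(self):
        a = AlignedBarcode("a", "ACGT" * 50)
        b = AlignedBarcode("b", "ACGT" * 50)
        for model in ("p", "jc69", "k2p"):
            d, n = pair_distance(a, b, model)
            assert d == 0.0 and n == 200

    def test_k2p_closed_form_10ts_5tv(self):
        base = ["A"] * 100
        other = base.copy()
        for i in range(10):
            _mutate(other, i, "ts")
        for i in range(10, 15):
            _mutate(other, i, "tv")
        d, n = pair_distance(AlignedBarcode("a", "".join(base)),
                             AlignedBarcode("b", "".join(other)), "k2p")
        assert n == 100
        assert d == pytest.approx(-0.5 * math.log(0.75 * math.sqrt(0.9)), abs=1e-12)
        assert d == pytest.approx(0.1702, abs=5e-5)

    def test_jc_closed_form_p01(self):
        base = ["A"] * 100
        other = base.copy()
        for i in range(10):
            _mutate(other, i, "ts")
        d, _ = pair_distance(AlignedBarcode("a", "".join(base)),
                             AlignedBarcode("b", "".join(other)), "jc69")
        assert d == pytest.approx(-0.75 * math.log(1 - 4 / 3 * 0.1), abs=1e-12)
        assert d == pytest.approx(0.1073, abs=5e-5)

    def test_ambiguity_gap_sites_excluded(self):
        # N, gap and IUPAC codes never count as transitions or transversions
        a = AlignedBarcode("a", "ACGTN-RA" + "A" * 100)
        b = AlignedBarcode("b", "ACGTACGG" + "A" * 100)
        d, n = pair_distance(a, b, "p")
        assert n == 105  # 3 masked columns
        assert d == pytest.approx(1 / 105)

    def test_too_few_comparable_sites_warns_nan(self):
        a = AlignedBarcode("a", "ACGT" + "N" * 200)
        b = AlignedBarcode("b", "ACGT" + "A" * 200)
        with pytest.warns(UserWarning, match="comparable sites"):
            d, n = pair_distance(a, b, "p")
        assert math.isnan(d) and n == 4

    def test_saturation_raises_unless_capped(self):
        a = AlignedBarcode("a", "A" * 100)
        b = AlignedBarcode("b", "G" * 100)  # all transitions: 1-2P-Q <= 0
        with pytest.raises(SaturationError):
            pair_distance(a, b, "k2p")
        d, _ = pair_distance(a, b, "k2p", saturation_cap=1.0)
        assert d == 1.0

    def test_agrees_with_counting_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        alphabet = np.array(list("ACGTACGTACGTN-"))  # missing chars at ~14%
        for _ in range(1000):
            L = int(rng.integers(150, 400))
            x = "".join(rng.choice(alphabet, size=L))
            y = "".join(np.where(rng.random(L) < 0.9, list(x), rng.choice(alphabet, size=L)))
            for model in ("p", "jc69", "k2p"):
                got, n_got = pair_distance(AlignedBarcode("x", x), AlignedBarcode("y", y),
                                           model, min_sites=10)
                exp, n_exp = oracle_distance(x, y, model)
                assert n_got == n_exp
                assert got == pytest.approx(exp, abs=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(ts=st.integers(0, 25), tv=st.integers(0, 25))
    def test_correction_monotonicity(self, ts, tv):
        """K2P >= JC69 >= p wherever all are defined."""
        base = ["A"] * 200
        other = base.copy()
        for i in range(ts):
            _mutate(other, i, "ts")
        for i in range(25, 25 + tv):
            _mutate(other, i, "tv")
        a, b = AlignedBarcode("a", "".join(base)), AlignedBarcode("b", "".join(other))
        d_p, _ = pair_distance(a, b, "p")
        d_jc, _ = pair_distance(a, b, "jc69")
        d_k2p, _ = pair_distance(a, b, "k2p")
        assert d_k2p >= d_jc - 1e-12
        assert d_jc >= d_p - 1e-12


class TestDistanceMatrix:
    def test_three_identical_sequences_zero_matrix(self):
        ds = make_dataset({"a": "ACGT" * 50, "b": "ACGT" * 50, "c": "ACGT" * 50})
        dm = distance_matrix(ds)
        assert np.all(dm.values == 0.0)

    def test_matrix_matches_pairwise_calls(self, five_species_dataset):
        ds = five_species_dataset
        dm = distance_matrix(ds, "k2p")
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        rng = np.random.default_rng(1)
        for _ in range(20):
            i, j = rng.integers(0, len(ds), size=2)
            d, n = pair_distance(ds.alignment[i], ds.alignment[j], "k2p")
            assert dm.values[i, j] == pytest.approx(d if i != j else 0.0, abs=1e-12)

    def test_two_cluster_separation(self, two_cluster_dataset):
        ds = two_cluster_dataset
        dm = distance_matrix(ds)
        near = [i for i, s in enumerate(dm.ids) if ds.species_of(s) == "near"]
        far = [i for i, s in enumerate(dm.ids) if ds.species_of(s) == "far"]
        within = max(dm.values[np.ix_(near, near)].max(), dm.values[np.ix_(far, far)].max())
        between = dm.values[np.ix_(near, far)].min()
        assert within < 0.03 < 0.05 < between


class TestRankSummaries:
    def test_strata_partition_all_pairs(self, five_species_dataset):
        ds = five_species_dataset
        dm = distance_matrix(ds)
        out = rank_summaries(dm, ds)
        n = len(ds)
        assert sum(s.n_comparisons for s in out) == n * (n - 1) // 2
        for s in out:
            if s.n_comparisons:
                assert s.min <= s.mean <= s.max

    def test_single_species_only_within_stratum(self):
        ds = make_dataset({"a": "ACGT" * 30, "b": "ACGA" * 30, "c": "ACGC" * 30})
        out = {s.stratum: s for s in rank_summaries(distance_matrix(ds), ds)}
        assert out["within_species"].n_comparisons == 3
        assert out["within_genus_between_species"].n_comparisons == 0
        assert out["between_tribes"].n_comparisons == 0

    def test_expected_stratum_counts(self):
        species = {"a": "X", "b": "X", "c": "Y", "d": "Z"}
        genus = {"a": "G1", "b": "G1", "c": "G1", "d": "G2"}
        tribe = {"a": "T1", "b": "T1", "c": "T1", "d": "T1"}
        ds = make_dataset({k: "ACGT" * 30 for k in "abcd"}, species, genus, tribe)
        out = {s.stratum: s.n_comparisons for s in rank_summaries(distance_matrix(ds), ds)}
        assert out == {"within_species": 1, "within_genus_between_species": 2,
                       "within_tribe_between_genera": 3, "between_tribes": 0}


class TestSpeciesLevelStats:
    def test_identical_pair_zero_max_intra(self):
        ds = make_dataset({"a": "ACGT" * 30, "b": "ACGT" * 30})
        dm = distance_matrix(ds)
        assert max_intraspecific(dm, ds) == {"SpA": 0.0}

    def test_singletons_excluded(self, five_species_dataset):
        ds = five_species_dataset
        mi = max_intraspecific(distance_matrix(ds), ds)
        counts = ds.to_frame()["morphospecies"].value_counts()
        assert set(mi) == set(counts[counts >= 2].index)

    def test_low_divergence_pairs_cutoff_zero_empty(self, five_species_dataset):
        ds = five_species_dataset
        assert low_divergence_pairs(distance_matrix(ds), ds, cutoff=0) == []

    def test_low_divergence_pairs_finds_constructed_pair(self):
        specs = [
            SpeciesSpec("close1", 3, 0.002, "G1", "T"),
            SpeciesSpec("close2", 3, 0.002, "G1", "T"),
            SpeciesSpec("other", 3, 0.002, "G2", "T"),
        ]
        cfg = SimConfig(species=specs, target_inter_congeneric=0.03, seed=9)
        ds = simulate_dataset(cfg)
        dm = distance_matrix(ds)
        pairs = low_divergence_pairs(dm, ds, cutoff=5.0)
        names = {(p.species_a, p.species_b) for p in pairs}
        assert ("close1", "close2") in names
        for p in pairs:
            assert p.min <= p.max

    def test_simulated_divergence_within_two_se_of_target(self):
        """Mean K2P across seeds tracks the generating branch length."""
        target = 0.05
        means = []
        for seed in range(12):
            specs = [SpeciesSpec("a", 2, target, "G", "T")]
            cfg = SimConfig(species=specs, target_inter_congeneric=0.2, seed=seed)
            ds = simulate_dataset(cfg)
            means.append(distance_matrix(ds).values[0, 1])
        m = np.mean(means)
        se = np.std(means, ddof=1) / math.sqrt(len(means))
        assert abs(m - target) < 2 * se + 0.002
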