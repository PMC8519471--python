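"""Simulated annealing: moves, acceptance, motif filters, oracle optimality."""

import math

import numpy as np
import pytest

from tisopt.anneal_opt import (
    AnnealConfig,
    anneal,
    count_search_space,
    exhaustive_optimum,
    metropolis_accept,
    motif_filter,
    propose,
    replaceable_positions,
)
from tisopt.core_seq import CodingConstruct, RegionSpec, translate

from conftest import make_energy_fn


def small_construct(seed: int = 0, n_variable: int = 4) -> CodingConstruct:
    """Short canonical construct with a controlled number of variable codons.

    Families: GCx (Ala, 4 synonyms), CGx (Arg-ish subset via CGT, 6), AAA
    (Lys, 2), GAT (Asp, 2) — enough degeneracy for annealing to matter while
    keeping exhaustive enumeration cheap.
    """
    rng = np.random.default_rng(seed)
    pool = ["GCT", "CGT", "AAA", "GAT", "CCG", "ACC"]
    body = "".join(rng.choice(pool) for _ in range(n_variable))
    utr5 = "".join(rng.choice(list("ACGT"), size=12))
    return CodingConstruct(f"toy{seed}", utr5, "ATG" + body + "TGG" + "TAA")


class TestReplaceablePositions:
    def test_first_nine_excludes_start(self):
        c = CodingConstruct("x", "", "ATG" + "GCT" * 18 + "TAA")
        assert replaceable_positions(c, 9) == list(range(2, 11))

    def test_full_excludes_start_and_stop(self):
        c = CodingConstruct("x", "", "ATG" + "GCT" * 3 + "TAA")
        assert replaceable_positions(c, None) == [2, 3, 4]

    def test_clipping_warns(self):
        c = CodingConstruct("x", "", "ATG" + "GCT" * 4 + "TAA")
        with pytest.warns(UserWarning, match="clipping"):
            assert replaceable_positions(c, 9) == [2, 3, 4, 5]


class TestSearchSpace:
    def test_nine_threefold_codons(self):
        # Ile (ATT) has exactly three synonyms
        c = CodingConstruct("x", "", "ATG" + "ATT" * 9 + "TAA")
        assert count_search_space(c, 9) == 3 ** 9 - 1 == 19_682

    def test_no_degeneracy_empty_space(self):
        c = CodingConstruct("x", "", "ATGTGGATGTAA")
        assert count_search_space(c, None) == 0

    def test_two_leucines(self):
        c = CodingConstruct("x", "", "ATGCTGCTGTAA")
        assert count_search_space(c, None) == 6 * 6 - 1 == 35


class TestPropose:
    def test_hot_move_touches_every_degenerate_codon(self):
        from tisopt.core_seq import synonymous_codons

        c = small_construct(1)
        codons = c.codons()
        replaceable = replaceable_positions(c, None)
        variable = [p for p in replaceable
                    if len(synonymous_codons(codons[p - 1])) > 1]
        rng = np.random.default_rng(0)
        out = propose(codons, temperature=1.0, t0=1.0,
                      replaceable=replaceable, rng=rng)
        changed = [p for p in replaceable if out[p - 1] != codons[p - 1]]
        assert changed == variable

    def test_cold_move_touches_one(self):
        c = small_construct(2)
        codons = c.codons()
        replaceable = replaceable_positions(c, None)
        rng = np.random.default_rng(0)
        out = propose(codons, temperature=1e-9, t0=1.0,
                      replaceable=replaceable, rng=rng)
        assert sum(a != b for a, b in zip(out, codons)) == 1

    def test_protein_always_conserved(self):
        c = small_construct(3)
        codons = c.codons()
        replaceable = replaceable_positions(c, None)
        rng = np.random.default_rng(1)
        for temperature in (1.0, 0.5, 0.1, 0.01):
            out = propose(codons, temperature, 1.0, replaceable, rng)
            assert translate("".join(out)) == translate(c.cds)


class TestMetropolis:
    def test_improving_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(1.0, 2.0, t, rng) for t in (1e-6, 0.5, 10))

    def test_half_acceptance_at_t_ln2(self):
        t = 0.7
        delta = t * math.log(2.0)
        rng = np.random.default_rng(123)
        accepted = sum(metropolis_accept(1.0 + delta, 1.0, t, rng)
                       for _ in range(10_000))
        assert accepted / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_rate_matches_boltzmann_factor(self):
        rng = np.random.default_rng(7)
        t, delta = 0.9, 1.3
        expected = math.exp(-delta / t)
        accepted = sum(metropolis_accept(2.0 + delta, 2.0, t, rng)
                       for _ in range(10_000))
        assert accepted / 10_000 == pytest.approx(expected, abs=0.02)


class TestMotifFilter:
    def test_forward_hit_reported(self):
        ok, hits = motif_filter("AAGGTCTCAA", ["GGTCTC"])
        assert not ok and hits[0] == ("GGTCTC", 2, "+")

    def test_reverse_complement_hit(self):
        ok, hits = motif_filter("TTGAGACCTT", ["GGTCTC"])
        assert not ok and hits[0][2] == "-"

    def test_empty_motif_list_always_passes(self):
        ok, hits = motif_filter("GGTCTCGGTCTC", [])
        assert ok and hits == []


class TestAnneal:
    def _config(self, seed, **kw):
        base = dict(n_codons=None, chains=4, max_iterations=400, patience=120,
                    seed=seed, scoring_region=RegionSpec(-8, 18))
        base.update(kw)
        return AnnealConfig(**base)

    def test_no_degeneracy_returns_input(self, toy_config):
        c = CodingConstruct("x", "ACGTACGTACGT", "ATG" + "TGGATG" * 3 + "TAA")
        config = self._config(0)
        energy_fn = make_energy_fn(c, config.scoring_region, toy_config)
        result = anneal(c, config, energy_fn)
        assert result.best.cds == c.cds
        assert result.best.n_substitutions == 0

    def test_best_energy_never_above_input(self, toy_config):
        for seed in range(5):
            c = small_construct(seed)
            config = self._config(seed)
            energy_fn = make_energy_fn(c, config.scoring_region, toy_config)
            result = anneal(c, config, energy_fn)
            assert result.best.energy <= result.input_energy + 1e-12

    def test_deterministic_for_seed(self, toy_config):
        c = small_construct(4)
        config = self._config(11)
        energy_fn = make_energy_fn(c, config.scoring_region, toy_config)
        a = anneal(c, config, energy_fn)
        b = anneal(c, config, energy_fn)
        assert [s.cds for s in a.solutions] == [s.cds for s in b.solutions]
        assert a.trajectories == b.trajectories

    def test_solutions_conserve_protein_and_pass_motifs(self, toy_config):
        c = small_construct(5)
        config = self._config(3)
        energy_fn = make_energy_fn(c, config.scoring_region, toy_config)
        result = anneal(c, config, energy_fn)
        for sol in result.solutions:
            assert translate(sol.cds) == translate(c.cds)
            assert motif_filter(c.utr5 + sol.cds, config.forbidden_motifs)[0]

    def test_finds_exhaustive_optimum_on_small_spaces(self, toy_config):
        """Annealing recovers the enumerated global optimum almost always."""
        hits = 0
        runs = 20
        for seed in range(runs):
            c = small_construct(seed + 100)
            config = self._config(seed)
            energy_fn = make_energy_fn(c, config.scoring_region, toy_config)
            _, best_energy = exhaustive_optimum(c, None, energy_fn)
            result = anneal(c, config, energy_fn)
            if result.best.energy <= best_energy + 1e-9:
                hits += 1
        assert hits / runs >= 0.95

    def test_oracle_is_lower_bound(self, toy_config):
        c = small_construct(200)
        config = self._config(1)
        energy_fn = make_energy_fn(c, config.scoring_region, toy_config)
        _, best_energy = exhaustive_optimum(c, None, energy_fn)
        for seed in range(3):
            result = anneal(c, self._config(seed), energy_fn)
            assert best_energy <= result.best.energy + 1e-9

    def test_preexisting_motif_does_not_freeze_search(self, toy_config):
        """A forbidden motif outside the window must not block every move."""
        c = CodingConstruct("m", "ACGTACGTACGT",
                            "ATG" + "GCTCGT" * 3 + "GGTCTC" + "TAA")
        config = self._config(0, scoring_region=RegionSpec(-8, 12))
        energy_fn = make_energy_fn(c, RegionSpec(-8, 12), toy_config)
        result = anneal(c, config, energy_fn)
        assert any("already contains" in note for note in result.warnings)
        assert any(s.n_substitutions > 0 for s in result.solutions)
        for sol in result.solutions:  # no *new* occurrences introduced
            _, hits = motif_filter(c.utr5 + sol.cds, config.forbidden_motifs)
            _, input_hits = motif_filter(c.sequence, config.forbidden_motifs)
            assert set(hits) <= set(input_hits)

    def test_target_objective_ranks_by_distance(self, toy_config):
        c = small_construct(7)
        config = self._config(2, objective="target", target_energy=5.0)
        energy_fn = make_energy_fn(c, config.scoring_region, toy_config)
        result = anneal(c, config, energy_fn)
        gaps = [abs(s.energy - 5.0) for s in result.solutions]
        assert gaps == sorted(gaps)


class TestExhaustive:
    def test_empty_space_returns_input(self, toy_config):
        c = CodingConstruct("x", "ACGTACGTACGT", "ATGTGGTAA")
        energy_fn = make_energy_fn(c, RegionSpec(-8, 9), toy_config)
        cds, energy = exhaustive_optimum(c, None, energy_fn)
        assert cds == c.cds

    def test_two_leucine_space_is_true_minimum(self, toy_config):
        import itertools

        from tisopt.core_seq import synonymous_codons

        c = CodingConstruct("x", "ACGTACGTACGT", "ATGCTGCTGTAA")
        energy_fn = make_energy_fn(c, RegionSpec(-8, 12), toy_config)
        _, best = exhaustive_optimum(c, None, energy_fn)
        leus = sorted(synonymous_codons("CTG"))
        manual = min(
            energy_fn("ATG" + a + b + "TAA")
            for a, b in itertools.product(leus, leus)
        )
        assert best == pytest.approx(manual)

    def test_oversized_space_refused(self, toy_config):
        c = CodingConstruct("x", "", "ATG" + "CTG" * 10 + "TAA")
        with pytest.raises(ValueError, match="exceeds"):
            exhaustive_optimum(c, None, lambda cds: 0.0, limit=1000)


class TestNineVersusFull:
    def test_nine_codon_window_approaches_full_length(self, toy_config):
        """Constraining substitutions to the first nine codons loses little.

        Mirror of the design question behind the nine-codon default: the
        distribution of optimized opening energies with a nine-codon window
        stays close to full-length optimization, and plain random synonymous
        substitution already improves over the input on average.
        """
        from tisopt.core_seq import random_construct, synonymous_codons
        from tisopt.expression_score import ks_distance

        region = RegionSpec(-16, 24)
        rng = np.random.default_rng(99)
        inputs, opt9, opt_full, randomized = [], [], [], []
        for seed in range(12):
            c = random_construct(16, utr5_len=16, seed=seed)
            energy_fn = make_energy_fn(c, region, toy_config)
            inputs.append(energy_fn(c.cds))
            for n_codons, sink in ((9, opt9), (None, opt_full)):
                config = AnnealConfig(
                    n_codons=n_codons, chains=2, max_iterations=150,
                    patience=60, seed=seed, scoring_region=region,
                )
                sink.append(anneal(c, config, energy_fn).best.energy)
            # random synonymous substitution of the same replaceable window
            draws = []
            for _ in range(5):
                codons = c.codons()
                for pos in replaceable_positions(c, None):
                    fam = sorted(synonymous_codons(codons[pos - 1]))
                    codons[pos - 1] = fam[rng.integers(len(fam))]
                draws.append(energy_fn("".join(codons)))
            randomized.append(float(np.mean(draws)))

        d = ks_distance(opt9, opt_full)
        assert d <= 0.4  # close distributions at this sample size
        assert np.mean(opt9) <= np.mean(randomized) + 1e-9
        assert np.mean(randomized) <= np.mean(inputs) + 1e-9
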