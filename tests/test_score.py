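"""Polygenic score engine: aPRS/wPRS arithmetic, standardization, binning."""
import itertools

import numpy as np
import pandas as pd
import pytest

from ldlprs.genotypes import APOE_GENOTYPES, GenotypeTable
from ldlprs.score import (ScoreDefinition, assign_decile, compute_aprs,
                          compute_scores, compute_wprs, percentile_rank,
                          percentile_threshold, standardize_scores)

NULLIFIED = ("rs6511720", "rs629301", "rs1800562")  # counted allele = common
RISK = ("rs1367117", "rs4299376", "rs2479409")      # counted allele = minor


def _dosages(nullified: int, risk: int) -> dict[str, int]:
    d = {rsid: nullified for rsid in NULLIFIED}
    d.update({rsid: risk for rsid in RISK})
    return d


class TestScoreArithmetic:
    def test_global_minimum(self, definition):
        # minor-homozygous at the nullified trio (0 counted common alleles),
        # common-homozygous at the risk trio, e2e2
        d = _dosages(nullified=2, risk=0)
        assert compute_aprs(d, "e2e2", definition) == -2
        assert compute_wprs(d, "e2e2", definition) == pytest.approx(-0.800)

    def test_global_maximum(self, definition):
        d = _dosages(nullified=0, risk=2)
        assert compute_aprs(d, "e4e4", definition) == 14
        assert compute_wprs(d, "e4e4", definition) == pytest.approx(1.482)

    def test_all_heterozygous_e3e3(self, definition):
        d = _dosages(nullified=1, risk=1)
        assert compute_aprs(d, "e3e3", definition) == 6

    def test_zero_score_genotype(self, definition):
        # every term zero: no counted alleles anywhere, neutral APOE
        d = _dosages(nullified=2, risk=0)
        assert compute_wprs(d, "e3e3", definition) == pytest.approx(0.0)

    def test_common_homozygous_everywhere_e2e3(self, definition):
        d = _dosages(nullified=0, risk=0)
        expected = 2 * (0.180 + 0.146 + 0.057) - 0.400
        assert compute_wprs(d, "e2e3", definition) == pytest.approx(expected)
        assert expected == pytest.approx(0.366)

    def test_missing_dosage_signals_exclusion(self, definition):
        d = _dosages(1, 1)
        d["rs1367117"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            compute_wprs(d, "e3e3", definition)


@pytest.fixture(scope="module")
def all_scores(definition):
    rsids = list(definition.snps)
    rows = []
    for combo in itertools.product((0, 1, 2), repeat=6):
        d = dict(zip(rsids, combo))
        for apoe in APOE_GENOTYPES:
            rows.append((compute_aprs(d, apoe, definition),
                         compute_wprs(d, apoe, definition)))
    return np.array(rows)


class TestExhaustiveEnumeration:

    def test_bounds_attained_over_all_genotypes(self, all_scores, definition):
        aprs, wprs = all_scores[:, 0], all_scores[:, 1]
        assert len(all_scores) == 3**6 * 6
        assert aprs.min() == -2 and aprs.max() == 14
        assert wprs.min() == pytest.approx(-0.800)
        assert wprs.max() == pytest.approx(1.482)
        lo, hi = definition.wprs_bounds()
        assert (lo, hi) == (pytest.approx(-0.800), pytest.approx(1.482))

    def test_per_allele_monotonicity_everywhere(self, definition):
        """+1 counted allele at any SNP raises wPRS by exactly its weight."""
        rsids = list(definition.snps)
        rng = np.random.default_rng(3)
        for _ in range(200):
            combo = dict(zip(rsids, rng.integers(0, 3, 6)))
            apoe = APOE_GENOTYPES[rng.integers(0, 6)]
            base = compute_wprs(combo, apoe, definition)
            for rsid in rsids:
                entry = definition.snps[rsid]
                step = -1 if entry.counted_allele == "common" else 1
                if combo[rsid] + step in (0, 1, 2):
                    bumped = dict(combo, **{rsid: combo[rsid] + step})
                    assert compute_wprs(bumped, apoe, definition) - base == pytest.approx(
                        entry.weight_per_allele)

    def test_snp_order_invariance(self, definition):
        d = _dosages(1, 2)
        shuffled = dict(reversed(list(d.items())))
        assert compute_wprs(d, "e3e4", definition) == compute_wprs(
            shuffled, "e3e4", definition)

    def test_weights_set_to_contributions_reproduce_aprs(self, definition):
        import yaml
        from importlib import resources
        cfg = yaml.safe_load(
            (resources.files("ldlprs.config") / "score_definition.yaml").read_text())
        for rsid in cfg["snps"]:
            cfg["snps"][rsid]["weight_per_allele"] = cfg["snps"][rsid]["aprs_per_allele"]
        for g in cfg["apoe"]:
            cfg["apoe"][g]["weight"] = cfg["apoe"][g]["aprs"]
        as_aprs = ScoreDefinition.from_dict(cfg)
        rng = np.random.default_rng(9)
        for _ in range(100):
            d = dict(zip(cfg["snps"], rng.integers(0, 3, 6)))
            apoe = APOE_GENOTYPES[rng.integers(0, 6)]
            assert compute_wprs(d, apoe, as_aprs) == pytest.approx(
                compute_aprs(d, apoe, definition))


class TestStandardization:
    def test_simple_example(self):
        z = standardize_scores([1.0, 2.0, 3.0])
        assert list(z) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            standardize_scores([2.0, 2.0, 2.0])

    def test_mean_zero_sd_one(self, rng):
        z = standardize_scores(rng.normal(5, 3, 500))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestPercentileBins:
    def test_deciles_on_1_to_100(self):
        scores = pd.Series(np.arange(1.0, 101.0))
        dec = assign_decile(scores)
        assert dec[scores == 95].iloc[0] == 10
        assert dec[scores == 5].iloc[0] == 1

    def test_all_tied_scores_fall_in_one_bin(self):
        dec = assign_decile([3.0] * 20)
        assert dec.nunique() == 1

    def test_decile_occupancy_balanced(self, rng):
        scores = rng.random(222)
        occ = assign_decile(scores).value_counts()
        assert occ.max() - occ.min() <= 1

    def test_percentile_rank_bounds_and_ties(self):
        r = percentile_rank([1.0, 1.0, 2.0])
        assert (r > 0).all() and (r < 100).all()
        assert r.iloc[0] == r.iloc[1]

    def test_threshold_uses_linear_interpolation(self):
        assert percentile_threshold([0.0, 10.0], 50) == pytest.approx(5.0)


class TestTableScoring:
    def test_table_scores_match_scalar_path(self, definition, small_cohort):
        genotypes, pheno = small_cohort
        scores = compute_scores(genotypes, definition)
        row = genotypes.dosage.iloc[17]
        d = {rsid: row[rsid] for rsid in definition.snps}
        from ldlprs.genotypes import call_apoe_genotype
        apoe = call_apoe_genotype(row["rs429358"], row["rs7412"])
        assert scores["wPRS"].iloc[17] == pytest.approx(
            compute_wprs(d, apoe, definition))
        assert scores["aPRS"].iloc[17] == compute_aprs(d, apoe, definition)

    def test_missing_genotype_flags_individual(self, definition):
        dosage = pd.DataFrame(
            {rsid: [1.0, 1.0] for rsid in list(definition.snps) + ["rs429358", "rs7412"]},
            index=["a", "b"],
        )
        dosage.loc["b", "rs629301"] = np.nan
        scores = compute_scores(GenotypeTable(dosage), definition)
        assert scores.loc["a", "complete"]
        assert not scores.loc["b", "complete"]
        assert np.isnan(scores.loc["b", "wPRS"])
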