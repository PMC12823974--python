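import numpy as np
import pandas as pd
import pytest

from bruteforce_oracles import bonferroni_adjust, pearson_pvalue, pearson_textbook
from npcoupling.classify import test_enrichment as enrichment_test
from npcoupling.classify import (
    classify_sites,
    classify_taxa,
    correlate_taxa,
    regress_vs_nmin_ap,
)
from npcoupling.constants import NUTRIENT_VARIABLES, VARIABLE_FAMILY
from npcoupling.exceptions import ValidationError
from npcoupling.preprocess import AggregatedTable
from npcoupling.tableio import NutrientTable


def _nutrients(n=35, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0, 0.4, n)
    data = {v: base * rng.lognormal(0, 0.3, n) for v in NUTRIENT_VARIABLES}
    return NutrientTable(
        pd.DataFrame(data, index=[f"S{i:02d}" for i in range(n)])
    )


def _agg(columns: dict, sites, group="16S"):
    frame = pd.DataFrame(columns, index=sites)
    return AggregatedTable(
        frame, rank="genus", group_of=pd.Series(group, index=frame.columns)
    )


class TestClassifySites:
    def test_threshold_rules(self):
        data = pd.DataFrame(
            {
                "TN": [4.7, 3.0, 5.0],
                "NAG": [1.0, 1.0, 1.0],
                "net_Nmin": [0.20, 0.20, 0.10],
                "N_inorg": [1.0, 1.0, 1.0],
                "TP": [1.0, 1.0, 1.0],
                "AP": [1.0, 1.0, 1.0],
                "AKP": [1.0, 1.0, 1.0],
            },
            index=["coupled_like", "edge_tn_tp", "low_nmin"],
        )
        out = classify_sites(NutrientTable(data))
        assert out.loc["coupled_like", "label"] == "coupled"  # 4.7 & 0.20
        assert out.loc["edge_tn_tp", "label"] == "decoupled"  # exactly 3.0 fails strict >
        assert out.loc["low_nmin", "label"] == "decoupled"  # 5.0 but 0.10

    def test_zero_tp_names_site(self):
        data = pd.DataFrame(
            {v: [1.0] for v in NUTRIENT_VARIABLES}, index=["S_bad"]
        )
        data.loc["S_bad", "TP"] = 0.0
        with pytest.raises(ValidationError, match="S_bad"):
            classify_sites(NutrientTable(data))


class TestCorrelateTaxa:
    def test_perfect_and_inverted_correlation(self):
        nut = _nutrients(20)
        agg = _agg(
            {"prop": 0.01 * nut.data["TN"], "anti": -0.01 * nut.data["TN"]},
            nut.sites,
        )
        rec = correlate_taxa(agg, nut).set_index(["taxon", "variable"])
        assert rec.loc[("prop", "TN"), "r"] == pytest.approx(1.0)
        assert rec.loc[("prop", "TN"), "p_adj"] < 1e-10
        assert rec.loc[("anti", "TN"), "r"] == pytest.approx(-1.0)

    def test_constant_taxon_excluded_from_family(self):
        nut = _nutrients(20)
        agg = _agg({"flat": [0.5] * 20, "var": nut.data["TN"]}, nut.sites)
        rec = correlate_taxa(agg, nut)
        flat = rec[rec.taxon == "flat"]
        assert not flat["computable"].any()
        assert flat["p_adj"].isna().all()
        # family size is the 7 computable tests of "var", not 14
        var_tn = rec[(rec.taxon == "var") & (rec.variable == "TN")].iloc[0]
        assert var_tn["p_adj"] == pytest.approx(min(1.0, var_tn["p_raw"] * 7))

    def test_needs_three_sites(self):
        nut = _nutrients(2)
        agg = _agg({"a": [0.1, 0.2]}, nut.sites)
        with pytest.raises(ValidationError):
            correlate_taxa(agg, nut)

    def test_type_one_error_controlled_for_independent_taxon(self):
        """An abundance vector independent of every nutrient variable should
        survive Bonferroni screening in >= 95% of simulations."""
        nut = _nutrients(35, seed=3)
        rng = np.random.default_rng(2024)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            agg = _agg({"null": rng.lognormal(0, 0.5, 35)}, nut.sites)
            rec = correlate_taxa(agg, nut, bonferroni="per_taxon")
            hits += bool(rec["significant"].any())
        assert hits / n_sim <= 0.05


class TestClassifyTaxa:
    def _records(self, spec):
        rows = []
        for taxon, entries in spec.items():
            for var, (r, p) in entries.items():
                rows.append(
                    {
                        "taxon": taxon,
                        "variable": var,
                        "family": VARIABLE_FAMILY[var],
                        "r": r,
                        "p_raw": p,
                        "p_adj": p,
                        "computable": True,
                        "significant": p < 0.05,
                    }
                )
        return pd.DataFrame(rows)

    def test_rule_partition(self):
        records = self._records(
            {
                "both_pos": {"TN": (0.70, 0.001), "TP": (0.65, 0.002), "AP": (0.1, 0.9)},
                "n_only": {"NAG": (-0.62, 0.004), "TP": (0.2, 0.6)},
                "p_only": {"AKP": (0.61, 0.01)},
                "mixed": {"TN": (0.70, 0.001), "TP": (-0.65, 0.002)},
                "quiet": {"TN": (0.30, 0.40)},
                "both_neg": {"N_inorg": (-0.7, 0.001), "AP": (-0.66, 0.003)},
            }
        )
        labels = classify_taxa(records).set_index("taxon")["label"]
        assert labels["both_pos"] == "coupled_positive"
        assert labels["n_only"] == "decoupled_N"
        assert labels["p_only"] == "decoupled_P"
        assert labels["mixed"] == "inconsistent"
        assert labels["quiet"] == "none"
        assert labels["both_neg"] == "coupled_negative"

    def test_alpha_monotonicity(self):
        """Raising alpha never moves a labeled taxon back to 'none'."""
        nut = _nutrients(35, seed=5)
        rng = np.random.default_rng(7)
        agg = _agg(
            {f"t{i}": nut.data["TN"] * rng.lognormal(0, s, 35) for i, s in
             enumerate([0.1, 0.3, 0.5, 0.8, 1.2, 2.0])},
            nut.sites,
        )
        rec = correlate_taxa(agg, nut)
        labeled = {}
        for alpha in (0.001, 0.01, 0.05, 0.2):
            lab = classify_taxa(rec, alpha=alpha)
            labeled[alpha] = set(lab.loc[lab.label != "none", "taxon"])
        assert labeled[0.001] <= labeled[0.01] <= labeled[0.05] <= labeled[0.2]

    def test_every_taxon_gets_exactly_one_label(self, dataset):
        from npcoupling.preprocess import aggregate

        agg = aggregate(dataset.counts["16S"], dataset.taxonomy, "genus")
        rec = correlate_taxa(agg, dataset.nutrients)
        labels = classify_taxa(rec)
        assert sorted(labels["taxon"]) == sorted(agg.taxa)
        assert labels["taxon"].is_unique


def test_labels_match_bruteforce_reimplementation(dataset):
    """Textbook double-loop Pearson + longhand Bonferroni + the written-out
    rule set reproduce the package labels exactly on a small table."""
    from npcoupling.preprocess import aggregate

    agg_full = aggregate(dataset.counts["phoD"], dataset.taxonomy, "genus")
    taxa = list(agg_full.taxa[:15])
    agg = _agg({t: agg_full.data[t] for t in taxa}, agg_full.data.index, "phoD")
    nut = dataset.nutrients
    rec = correlate_taxa(agg, nut)
    labels = classify_taxa(rec).set_index("taxon")["label"]

    raw_p, keys, rs = [], [], []
    for t in taxa:
        for v in NUTRIENT_VARIABLES:
            r = pearson_textbook(list(agg.data[t]), list(nut.data.loc[agg.data.index, v]))
            raw_p.append(pearson_pvalue(r, agg.n_sites))
            keys.append((t, v))
            rs.append(r)
    adj = bonferroni_adjust(raw_p)
    for t in taxa:
        sig = [
            (VARIABLE_FAMILY[v], r)
            for (tt, v), r, q in zip(keys, rs, adj)
            if tt == t and q < 0.05
        ]
        fams = {f for f, _ in sig}
        signs = {1 if r > 0 else -1 for _, r in sig}
        if fams == {"N", "P"}:
            expect = (
                "coupled_positive" if signs == {1}
                else "coupled_negative" if signs == {-1}
                else "inconsistent"
            )
        elif fams == {"N"}:
            expect = "decoupled_N"
        elif fams == {"P"}:
            expect = "decoupled_P"
        else:
            expect = "none"
        assert labels[t] == expect


class TestRegression:
    def test_exact_linear_relationship(self):
        nut = _nutrients(20)
        ratio = nut.data["net_Nmin"] / nut.data["AP"]
        agg = _agg({"lin": 0.01 * ratio + 0.002, "noise": np.linspace(0, 1, 20)}, nut.sites)
        labels = pd.DataFrame(
            {"taxon": ["lin", "noise"], "label": ["coupled_positive", "none"]}
        )
        out = regress_vs_nmin_ap(agg, nut, labels).set_index("taxon")
        assert out.loc["lin", "r_squared"] == pytest.approx(1.0)
        assert out.loc["lin", "slope"] == pytest.approx(0.01)
        assert "noise" not in out.index  # only coupled taxa are tested

    def test_bonferroni_over_coupled_taxa(self):
        nut = _nutrients(30, seed=9)
        rng = np.random.default_rng(0)
        agg = _agg({f"c{i}": rng.lognormal(0, 0.5, 30) for i in range(4)}, nut.sites)
        labels = pd.DataFrame(
            {"taxon": [f"c{i}" for i in range(4)], "label": ["coupled_positive"] * 4}
        )
        out = regress_vs_nmin_ap(agg, nut, labels)
        assert np.allclose(out["p_adj"], np.minimum(1.0, out["p_raw"] * 4))


class TestEnrichment:
    def _setup(self, coupled_high=True):
        sites = [f"S{i}" for i in range(15)]
        site_labels = pd.DataFrame(
            {"label": ["coupled"] * 5 + ["decoupled"] * 10}, index=sites
        )
        # distinct values keep the rank test exact (no tie correction)
        hi, lo = (
            ([20.0, 21, 22, 23, 24], list(map(float, range(1, 11))))
            if coupled_high
            else ([3.0] * 5, [3.0] * 10)
        )
        agg = _agg({"tax": hi + lo}, sites)
        labels = pd.DataFrame({"taxon": ["tax"], "label": ["coupled_positive"]})
        return agg, site_labels, labels

    def test_complete_separation_minimal_p(self):
        agg, site_labels, labels = self._setup(True)
        out = enrichment_test(agg, site_labels, labels)
        # all coupled ranks above all decoupled: p = 1 / C(15,5)
        assert out["p_raw"].iloc[0] == pytest.approx(1 / 3003, rel=1e-6)
        assert bool(out["enriched"].iloc[0])

    def test_identical_distributions_not_enriched(self):
        agg, site_labels, labels = self._setup(False)
        out = enrichment_test(agg, site_labels, labels)
        assert not out["enriched"].iloc[0]

    def test_empty_site_class_rejected(self):
        agg, site_labels, labels = self._setup(True)
        site_labels["label"] = "coupled"
        with pytest.raises(ValidationError):
            enrichment_test(agg, site_labels, labels)
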