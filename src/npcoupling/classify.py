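"""Site and taxon classification for coupled vs decoupled N-P cycling.

Sites are "coupled" when both stoichiometric ratios clear their thresholds
strictly (TN/TP > 3 and net_Nmin/AP > 0.16). Taxa are screened by Pearson
correlation of relative abundance against the seven nutrient variables with
Bonferroni adjustment; a taxon significant in both families with one
consistent sign is coupled (positive or negative), significant in exactly one
family decoupled (N or P), significant in both with mixed signs
"inconsistent", and otherwise "none". Coupled taxa are further annotated by
an OLS regression on net_Nmin/AP and a one-sided rank test for enrichment in
coupled sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .constants import NUTRIENT_VARIABLES, VARIABLE_FAMILY
from .exceptions import ValidationError
from .preprocess import AggregatedTable
from .tableio import NutrientTable

COUPLED_SITE_TN_TP = 3.0
COUPLED_SITE_NMIN_AP = 0.16


def classify_sites(
    nutrients: NutrientTable,
    tn_tp_min: float = COUPLED_SITE_TN_TP,
    nmin_ap_min: float = COUPLED_SITE_NMIN_AP,
) -> pd.DataFrame:
    """Label each site coupled/decoupled from its stoichiometric ratios.

    Returns a frame indexed by site with columns ``tn_tp``, ``nmin_ap`` and
    ``label``; both inequalities are strict. Sites with TP or AP equal to 0
    are rejected (the ratio is undefined). net_Nmin may be nonpositive — the
    28-day net change can be negative — only the comparison with the
    threshold matters.
    """
    data = nutrients.data
    for var in ("TP", "AP"):
        zero = data.index[data[var] <= 0]
        if len(zero):
            raise ValidationError(f"{var} must be positive; offending site {zero[0]!r}")
    tn_tp = data["TN"] / data["TP"]
    nmin_ap = data["net_Nmin"] / data["AP"]
    label = np.where((tn_tp > tn_tp_min) & (nmin_ap > nmin_ap_min), "coupled", "decoupled")
    return pd.DataFrame(
        {"tn_tp": tn_tp, "nmin_ap": nmin_ap, "label": label}, index=data.index
    )


def _align_sites(agg: AggregatedTable, nutrients: NutrientTable) -> pd.DataFrame:
    missing = agg.data.index.difference(nutrients.sites)
    if len(missing):
        raise ValidationError(f"nutrient table missing site {missing[0]!r}")
    return nutrients.data.loc[agg.data.index]


def correlate_taxa(
    agg: AggregatedTable,
    nutrients: NutrientTable,
    alpha: float = 0.05,
    bonferroni: str = "family",
) -> pd.DataFrame:
    """Pearson r of every taxon against the seven nutrient variables.

    ``bonferroni='family'`` adjusts over all computable taxon x variable tests
    in this call (one marker group at one rank is the intended family);
    ``'per_taxon'`` adjusts over each taxon's own seven tests as a
    sensitivity mode. Constant vectors yield non-computable records that are
    excluded from the family size.
    """
    if agg.n_sites < 3:
        raise ValidationError("correlation screening needs at least 3 sites")
    if bonferroni not in ("family", "per_taxon"):
        raise ValidationError(f"unknown bonferroni mode {bonferroni!r}")
    nut = _align_sites(agg, nutrients)
    n = agg.n_sites

    X = agg.data.to_numpy(dtype=float)
    Y = nut.to_numpy(dtype=float)
    x_sd = X.std(axis=0, ddof=0)
    y_sd = Y.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xz = (X - X.mean(axis=0)) / x_sd
        Yz = (Y - Y.mean(axis=0)) / y_sd
        R = Xz.T @ Yz / n
    computable = np.outer(x_sd > 0, y_sd > 0)
    R = np.clip(R, -1.0, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1e-300, 1 - R**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(R), 1.0), 0.0, p)

    rows = []
    taxa = agg.taxa
    for i, taxon in enumerate(taxa):
        for j, var in enumerate(NUTRIENT_VARIABLES):
            ok = bool(computable[i, j])
            rows.append(
                {
                    "taxon": taxon,
                    "variable": var,
                    "family": VARIABLE_FAMILY[var],
                    "r": R[i, j] if ok else np.nan,
                    "p_raw": p[i, j] if ok else np.nan,
                    "computable": ok,
                }
            )
    records = pd.DataFrame(rows)
    if bonferroni == "family":
        m = int(records["computable"].sum())
        records["p_adj"] = np.minimum(1.0, records["p_raw"] * max(m, 1))
    else:
        m_per = records.groupby("taxon")["computable"].transform("sum")
        records["p_adj"] = np.minimum(1.0, records["p_raw"] * m_per.clip(lower=1))
    records["significant"] = records["computable"] & (records["p_adj"] < alpha)
    return records


def classify_taxa(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Assign one coupling label per taxon from its correlation records.

    Every taxon receives exactly one label; the rule set partitions the
    possibilities (see module docstring). Deterministic given the records.
    """
    rows = []
    for taxon, grp in records.groupby("taxon", sort=False):
        sig = grp[grp["computable"] & (grp["p_adj"] < alpha)]
        n_sig_n = int((sig["family"] == "N").sum())
        n_sig_p = int((sig["family"] == "P").sum())
        signs = set(np.sign(sig["r"]).astype(int))
        if n_sig_n and n_sig_p:
            if signs == {1}:
                label = "coupled_positive"
            elif signs == {-1}:
                label = "coupled_negative"
            else:
                label = "inconsistent"
        elif n_sig_n:
            label = "decoupled_N"
        elif n_sig_p:
            label = "decoupled_P"
        else:
            label = "none"
        rows.append(
            {"taxon": taxon, "label": label, "n_sig_N": n_sig_n, "n_sig_P": n_sig_p}
        )
    return pd.DataFrame(rows, columns=["taxon", "label", "n_sig_N", "n_sig_P"])


def regress_vs_nmin_ap(
    agg: AggregatedTable,
    nutrients: NutrientTable,
    labels: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """OLS of each coupled taxon's relative abundance on net_Nmin/AP.

    Bonferroni adjustment runs over the number of coupled taxa tested. The
    ratio reflects the coupled N-P process more directly than TN/TP, hence
    its use as the regressor.
    """
    if agg.n_sites < 3:
        raise ValidationError("regression needs at least 3 sites")
    nut = _align_sites(agg, nutrients)
    if (nut["AP"] <= 0).any():
        bad = nut.index[nut["AP"] <= 0][0]
        raise ValidationError(f"AP must be positive; offending site {bad!r}")
    ratio = (nut["net_Nmin"] / nut["AP"]).to_numpy()
    coupled = labels.loc[
        labels["label"].isin(("coupled_positive", "coupled_negative")), "taxon"
    ].tolist()
    rows = []
    for taxon in coupled:
        y = agg.data[taxon].to_numpy(dtype=float)
        fit = stats.linregress(ratio, y)
        rows.append(
            {
                "taxon": taxon,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.rvalue**2,
                "p_raw": fit.pvalue,
            }
        )
    out = pd.DataFrame(
        rows, columns=["taxon", "slope", "intercept", "r_squared", "p_raw"]
    )
    m = max(len(out), 1)
    out["p_adj"] = np.minimum(1.0, out["p_raw"] * m)
    out["significant"] = out["p_adj"] < alpha
    return out


def test_enrichment(
    agg: AggregatedTable,
    site_labels: pd.DataFrame,
    labels: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Mann-Whitney test (coupled sites > decoupled sites) per
    coupled taxon, Benjamini-Hochberg adjusted across the taxa tested."""
    lab = site_labels.loc[agg.data.index, "label"]
    coupled_sites = lab[lab == "coupled"].index
    decoupled_sites = lab[lab == "decoupled"].index
    if len(coupled_sites) == 0 or len(decoupled_sites) == 0:
        raise ValidationError("both site classes must be nonempty for enrichment tests")
    coupled_taxa = labels.loc[
        labels["label"].isin(("coupled_positive", "coupled_negative")), "taxon"
    ].tolist()
    rows = []
    for taxon in coupled_taxa:
        a = agg.data.loc[coupled_sites, taxon].to_numpy(dtype=float)
        b = agg.data.loc[decoupled_sites, taxon].to_numpy(dtype=float)
        stat = stats.mannwhitneyu(a, b, alternative="greater")
        rows.append(
            {
                "taxon": taxon,
                "mean_coupled": a.mean(),
                "mean_decoupled": b.mean(),
                "p_raw": stat.pvalue,
            }
        )
    out = pd.DataFrame(rows, columns=["taxon", "mean_coupled", "mean_decoupled", "p_raw"])
    if len(out):
        out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    else:
        out["p_adj"] = pd.Series(dtype=float)
    out["enriched"] = out["p_adj"] < alpha
    return out
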