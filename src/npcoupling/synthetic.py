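"""Synthetic soil-community generator with known planted structure.

Emulates a 35-site amplicon survey of three marker groups (16S bacteria, ITS
fungi, phoD-harboring bacteria) together with the seven N- and P-cycling soil
variables, so the whole inference chain — site classification, taxon coupling
labels, signed co-occurrence networks — can be exercised and scored against a
ground truth without any external sequencing data.

Model sketch
------------
Sites get latent N- and P-cycling "speed" factors; a chosen number of sites is
drawn above both stoichiometric thresholds (TN/TP > 3 and net_Nmin/AP > 0.16)
and the rest fail at least one. Taxa are organized into synthetic genera
(>= 3 features each) nested in phyla. Each genus carries one planted label:

* ``coupled_positive`` / ``coupled_negative`` — latent abundance tracks a
  combination of one N-variable and one P-variable (the most positively
  correlated cross-family pair, so the dual target is attainable) with target
  Pearson correlation ``target_r`` (sign per label),
* ``decoupled_N`` / ``decoupled_P`` — tracks a single variable of one family,
  chosen as the family member least correlated with the other family,
* ``none`` — independent of every nutrient variable.

Latent abundances are log-normal perturbations of linear combinations of the
standardized anchor variables; the correlation targeting is approximate and
compensates analytically for log-normal attenuation. Counts are multinomial
allocations of each site's sequencing depth to the latent proportions, so
column (site) sums equal the drawn depths exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from .constants import GROUP_DOMAIN, MARKER_GROUPS, N_VARIABLES, P_VARIABLES
from .exceptions import ConfigError
from .tableio import CountTable, NutrientTable, TaxonomyMap

#: log-scale dispersion of latent abundances around the anchor signal
SIGMA_L = 0.4

#: coupled-site TN/TP is drawn from this interval (mean 4.70)
COUPLED_TN_TP = (3.4, 6.0)
DECOUPLED_TN_TP = (0.8, 2.7)
COUPLED_NMIN_AP = (0.18, 0.40)
DECOUPLED_NMIN_AP = (0.02, 0.14)

TN_TP_MIN = 3.0
NMIN_AP_MIN = 0.16


@dataclass
class GeneratorConfig:
    """Study-design parameters for one synthetic dataset."""

    n_sites: int = 35
    n_taxa_per_group: dict[str, int] = field(
        default_factory=lambda: {"16S": 120, "ITS": 80, "phoD": 48}
    )
    fraction_coupled: float = 0.20
    fraction_decoupled_N: float = 0.15
    fraction_decoupled_P: float = 0.15
    target_r: float = 0.85
    depth_range: tuple[int, int] = (30_000, 65_000)
    n_coupled_sites: int = 10
    noise_sd: float = 0.5
    coupled_site_boost: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        fracs = (
            self.fraction_coupled,
            self.fraction_decoupled_N,
            self.fraction_decoupled_P,
        )
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ConfigError("label fractions must be nonnegative and sum to <= 1")
        if not 0 < self.target_r < 1:
            raise ConfigError("target_r must lie in (0, 1)")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ConfigError("depth_range must satisfy 1 <= min <= max")
        if self.n_coupled_sites > self.n_sites:
            raise ConfigError(
                f"n_coupled_sites ({self.n_coupled_sites}) exceeds n_sites ({self.n_sites})"
            )
        if self.n_sites < 3:
            raise ConfigError("need at least 3 sites")
        unknown = set(self.n_taxa_per_group) - set(MARKER_GROUPS)
        if unknown:
            raise ConfigError(f"unknown marker groups in n_taxa_per_group: {unknown}")
        if any(n < 3 for n in self.n_taxa_per_group.values()):
            raise ConfigError("each marker group needs at least 3 features")
        if self.noise_sd < 0 or self.coupled_site_boost <= 0:
            raise ConfigError("noise_sd must be >= 0 and coupled_site_boost > 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated dataset.

    ``features``: per-feature planted label and anchors (index feature_id);
    ``genera``: the same at the genus level, where labels are planted;
    ``sites``: true coupled/decoupled site labels; ``seed``: generator seed.
    """

    features: pd.DataFrame
    genera: pd.DataFrame
    sites: pd.Series
    seed: int


def _site_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def generate_nutrients(config: GeneratorConfig) -> NutrientTable:
    """Draw the seven-variable nutrient table with planted site classes.

    Exactly ``n_coupled_sites`` sites land strictly above both thresholds
    (TN/TP > 3, net_Nmin/AP > 0.16); every other site fails at least one,
    via one of three decoupling modes (slow N, slow P mineralization, or
    both). N-cycling variables share a latent factor with heavier loadings
    than their cross-family links, so they cluster more tightly with each
    other than with the P-cycling variables.
    """
    config.validate()
    n = config.n_sites
    rng = default_rng(SeedSequence(config.seed, spawn_key=(0,)))

    coupled = np.zeros(n, dtype=bool)
    coupled[rng.choice(n, size=config.n_coupled_sites, replace=False)] = True

    g = rng.normal(0.0, 0.6, n) + 1.5 * coupled  # N-cycling speed
    h = 0.5 * g + rng.normal(0.0, 0.5, n) + 0.8 * coupled  # P-cycling speed

    def lognorm(mu: float, load: float, factor: np.ndarray, sd: float) -> np.ndarray:
        return np.exp(np.log(mu) + load * factor + rng.normal(0.0, sd, n))

    tn = lognorm(0.30, 0.55, g, 0.18)  # % mass
    nag = lognorm(40.0, 0.50, g, 0.20)  # enzyme activity
    n_inorg = lognorm(18.0, 0.50, g, 0.20)  # mg/kg
    net_nmin = lognorm(2.5, 0.50, g, 0.20)  # mg/kg over 28 d
    akp = lognorm(250.0, 0.45, h, 0.25)  # enzyme activity

    # Stoichiometric ratios are planted directly so the site classes are exact.
    r_tn_tp = np.where(
        coupled,
        rng.uniform(*COUPLED_TN_TP, n),
        rng.uniform(*DECOUPLED_TN_TP, n),
    )
    r_nmin_ap = np.where(
        coupled,
        rng.uniform(*COUPLED_NMIN_AP, n),
        rng.uniform(*DECOUPLED_NMIN_AP, n),
    )
    mode = rng.integers(0, 3, n)  # decoupling mode: 0 slow N, 1 slow P, 2 both
    high_tn_tp = rng.uniform(*COUPLED_TN_TP, n)
    high_nmin_ap = rng.uniform(*COUPLED_NMIN_AP, n)
    r_tn_tp = np.where(~coupled & (mode == 1), high_tn_tp, r_tn_tp)
    r_nmin_ap = np.where(~coupled & (mode == 0), high_nmin_ap, r_nmin_ap)

    tp = tn / r_tn_tp
    ap = net_nmin / r_nmin_ap

    data = pd.DataFrame(
        {
            "TN": tn,
            "NAG": nag,
            "net_Nmin": net_nmin,
            "N_inorg": n_inorg,
            "TP": tp,
            "AP": ap,
            "AKP": akp,
        },
        index=pd.Index(_site_ids(n), name="site_id"),
    )
    return NutrientTable(data)


def _partition_sizes(total: int, rng, low: int, high: int) -> list[int]:
    """Split ``total`` into chunks of low..high items, folding a short tail."""
    sizes: list[int] = []
    remaining = total
    while remaining > 0:
        k = int(rng.integers(low, high + 1))
        if remaining - k < low and remaining - k > 0:
            k = remaining
        k = min(k, remaining)
        sizes.append(k)
        remaining -= k
    return sizes


def _genus_labels(n_genera: int, config: GeneratorConfig) -> list[str]:
    n_coupled = round(config.fraction_coupled * n_genera)
    n_dn = round(config.fraction_decoupled_N * n_genera)
    n_dp = round(config.fraction_decoupled_P * n_genera)
    labels = []
    for i in range(n_coupled):
        labels.append("coupled_positive" if i % 3 != 2 else "coupled_negative")
    labels += ["decoupled_N"] * n_dn + ["decoupled_P"] * n_dp
    labels += ["none"] * (n_genera - len(labels))
    return labels[:n_genera]


def _pick_decoupled_anchor(z: pd.DataFrame, family: tuple[str, ...], other: tuple[str, ...]) -> str:
    """Family member with the weakest worst-case leakage into the other family."""
    corr = z.corr()
    leak = {v: corr.loc[v, list(other)].abs().max() for v in family}
    return min(leak, key=lambda v: (leak[v], v))


def _pick_coupled_anchors(z: pd.DataFrame) -> tuple[str, str, float]:
    """Most positively correlated (N-variable, P-variable) pair.

    A taxon can correlate at r with both members of a pair only when the pair
    itself correlates at >= 2 r^2 - 1, so the dual-family signal is planted on
    the cross-family pair where the target is most nearly attainable.
    """
    corr = z.corr()
    best = max(
        ((nv, pv) for nv in N_VARIABLES for pv in P_VARIABLES),
        key=lambda pair: (corr.loc[pair[0], pair[1]], pair),
    )
    return best[0], best[1], float(corr.loc[best[0], best[1]])


def generate_counts(
    config: GeneratorConfig, nutrients: NutrientTable
) -> tuple[dict[str, CountTable], TaxonomyMap, SyntheticTruth]:
    """Generate per-group count tables, a taxonomy map, and the truth sidecar.

    Each marker group uses its own random stream (documented sub-seeds of the
    config seed), so enlarging one group leaves the others bit-identical.
    """
    config.validate()
    sites = nutrients.sites
    if len(sites) != config.n_sites:
        raise ConfigError("nutrient table does not cover the configured sites")
    n = config.n_sites

    raw = nutrients.data
    z = (raw - raw.mean()) / raw.std(ddof=0)
    atten = SIGMA_L / np.sqrt(np.expm1(SIGMA_L**2))
    anchor_dn = _pick_decoupled_anchor(z, N_VARIABLES, P_VARIABLES)
    anchor_dp = _pick_decoupled_anchor(z, P_VARIABLES, N_VARIABLES)
    anchor_cn, anchor_cp, rho = _pick_coupled_anchors(raw)

    s_coupled = (z[anchor_cn] + z[anchor_cp]).to_numpy()
    s_coupled = s_coupled / s_coupled.std()
    c_coupled = min(1.0, config.target_r / (atten * np.sqrt((1 + max(rho, -0.5)) / 2)))
    c_single = min(1.0, config.target_r / atten)

    coupled_sites = (
        (raw["TN"] / raw["TP"] > TN_TP_MIN) & (raw["net_Nmin"] / raw["AP"] > NMIN_AP_MIN)
    ).to_numpy()

    tables: dict[str, CountTable] = {}
    tax_rows: list[dict] = []
    feat_rows: list[dict] = []
    genus_rows: list[dict] = []

    for gi, group in enumerate(MARKER_GROUPS):
        n_feat = config.n_taxa_per_group.get(group, 0)
        if n_feat == 0:
            continue
        rng = default_rng(SeedSequence(config.seed, spawn_key=(1 + gi,)))
        genus_sizes = _partition_sizes(n_feat, rng, 3, 5)
        n_genera = len(genus_sizes)
        phylum_sizes = _partition_sizes(n_genera, rng, 3, 7)
        labels = _genus_labels(n_genera, config)

        genus_names = [f"{group}_gen{j + 1:03d}" for j in range(n_genera)]
        phylum_of: dict[str, str] = {}
        start = 0
        for pj, psize in enumerate(phylum_sizes):
            for gname in genus_names[start : start + psize]:
                phylum_of[gname] = f"{group}_phy{pj + 1:02d}"
            start += psize

        # Exercise the placeholder convention on one signal-free genus.
        placeholder: dict[str, str] = {}
        for j, lab in enumerate(labels):
            if lab == "none":
                placeholder[genus_names[j]] = f"unclassified_{phylum_of[genus_names[j]]}"
                break

        w = np.empty((n, n_feat))
        col = 0
        kingdom = {"bacteria": "Bacteria", "fungi": "Fungi", "phoD": "Bacteria"}[
            GROUP_DOMAIN[group]
        ]
        for j, (gname, size, label) in enumerate(zip(genus_names, genus_sizes, labels)):
            if label in ("coupled_positive", "coupled_negative"):
                sign = 1.0 if label == "coupled_positive" else -1.0
                s, c = sign * s_coupled, c_coupled
                anchor_n, anchor_p = anchor_cn, anchor_cp
            elif label == "decoupled_N":
                s, c = z[anchor_dn].to_numpy(), c_single
                anchor_n, anchor_p = anchor_dn, ""
            elif label == "decoupled_P":
                s, c = z[anchor_dp].to_numpy(), c_single
                anchor_n, anchor_p = "", anchor_dp
            else:
                s, c = np.zeros(n), 0.0
                anchor_n = anchor_p = ""
            x_genus = c * s + np.sqrt(max(0.0, 1 - c**2)) * rng.normal(size=n)
            genus_scale = np.exp(rng.normal(0.0, 1.0))

            out_name = placeholder.get(gname, gname)
            genus_rows.append(
                {
                    "genus": out_name,
                    "marker_group": group,
                    "planted_label": label,
                    "target_r": config.target_r if label.startswith(("coupled", "decoupled")) else 0.0,
                    "anchor_N": anchor_n,
                    "anchor_P": anchor_p,
                }
            )
            for k in range(size):
                feat = f"{group}_ASV{col + 1:04d}"
                base = genus_scale * np.exp(rng.normal(0.0, 0.5))
                eta = rng.normal(size=n)
                w[:, col] = base * np.exp(SIGMA_L * (x_genus + config.noise_sd * eta))
                if label == "coupled_positive":
                    w[coupled_sites, col] *= config.coupled_site_boost
                elif label == "coupled_negative":
                    w[coupled_sites, col] /= config.coupled_site_boost
                phylum = phylum_of[gname]
                tax_rows.append(
                    {
                        "feature_id": feat,
                        "kingdom": kingdom,
                        "phylum": phylum,
                        "class": f"c_{phylum}",
                        "order": f"o_{phylum}",
                        "family": f"f_{out_name}",
                        "genus": out_name,
                        "species": f"s_{feat}",
                    }
                )
                feat_rows.append(
                    {
                        "feature_id": feat,
                        "marker_group": group,
                        "genus": out_name,
                        "phylum": phylum,
                        "planted_label": label,
                        "target_r": config.target_r if label != "none" else 0.0,
                        "anchor_N": anchor_n,
                        "anchor_P": anchor_p,
                    }
                )
                col += 1

        depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1, n)
        counts = np.empty((n, n_feat), dtype=np.int64)
        for i in range(n):
            pi = w[i] / w[i].sum()
            counts[i] = rng.multinomial(depths[i], pi)
        features = [f"{group}_ASV{k + 1:04d}" for k in range(n_feat)]
        tables[group] = CountTable(
            pd.DataFrame(counts, index=sites, columns=features), marker_group=group
        )

    taxonomy = TaxonomyMap(pd.DataFrame(tax_rows).set_index("feature_id"))
    truth = SyntheticTruth(
        features=pd.DataFrame(feat_rows).set_index("feature_id"),
        genera=pd.DataFrame(genus_rows).set_index("genus"),
        sites=pd.Series(
            np.where(coupled_sites, "coupled", "decoupled"), index=sites, name="site_label"
        ),
        seed=config.seed,
    )
    return tables, taxonomy, truth


@dataclass
class SyntheticDataset:
    counts: dict[str, CountTable]
    taxonomy: TaxonomyMap
    nutrients: NutrientTable
    truth: SyntheticTruth


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Convenience wrapper: nutrients, counts, taxonomy, and truth in one call."""
    nutrients = generate_nutrients(config)
    counts, taxonomy, truth = generate_counts(config, nutrients)
    return SyntheticDataset(counts, taxonomy, nutrients, truth)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Tab-delimited truth sidecar (feature_id, planted_label, target_r, ...)."""
    out = truth.features.reset_index()[
        ["feature_id", "planted_label", "target_r", "marker_group", "genus", "phylum", "anchor_N", "anchor_P"]
    ]
    out.to_csv(path, sep="\t", index=False)
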