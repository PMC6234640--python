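"""Synthetic multi-population panels, genotypes and disease-locus tables.

The generator emulates the statistical structure that the downstream
analysis leans on: standing neutral variation with an SFS-shaped
ancestral frequency distribution, a low-drift African population and
four bottlenecked non-African populations diverging under a
hierarchical Balding–Nichols model, small-discovery-panel array
ascertainment, Hardy–Weinberg genotypes, and a category-labelled
disease-locus table with ancestral or derived risk alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import DAF_COLUMNS, NON_AFRICAN, POPULATIONS, Panel, _PANEL_COLUMNS

#: The seven non-overlapping disease categories used throughout.
CATEGORIES: tuple[str, ...] = (
    "GI/liver",
    "metabolic",
    "morphological",
    "cancer",
    "neurological",
    "miscellaneous",
    "cardiovascular",
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DemographyParams:
    """Drift coefficients of the hierarchical out-of-Africa divergence model.

    The African population diverges from the ancestral frequency with
    drift ``f_afr``; the four non-African populations pass through a
    shared bottleneck (``f_ooa``) and then drift independently by
    ``f_pop`` each.  Under Balding–Nichols, a population frequency given
    ancestral frequency p0 is Beta with mean p0 and variance
    ``f * p0 * (1 - p0)``, so the invariant ``f_ooa > f_afr`` encodes
    the greater drift of bottlenecked non-African populations.
    """

    n_snps: int = 50_000
    f_afr: float = 0.01
    f_ooa: float = 0.10
    f_pop: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f_afr", "f_ooa", "f_pop"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name}={f} must be in (0,1)")
        if self.f_ooa <= self.f_afr:
            raise ValueError("f_ooa must exceed f_afr (non-African drift is greater)")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")


@dataclass(frozen=True)
class DiseaseLocus:
    """A variant flagged as disease-associated."""

    id: str
    risk_allele_state: str  # "ancestral" | "derived"
    category: str
    grr: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.risk_allele_state not in ("ancestral", "derived"):
            raise ValueError(f"risk_allele_state {self.risk_allele_state!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.grr is not None and any(g < 1 for g in self.grr.values()):
            raise ValueError("genotype relative risks must be >= 1")


def sample_ancestral_frequency(n: int, n_chrom: int = 1000, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ancestral derived-allele frequencies from the neutral SFS.

    Frequencies live on the grid ``{1/n_chrom, ..., (n_chrom-1)/n_chrom}``
    with probability proportional to ``1/i`` — the standing-variation
    spectrum of a constant-size neutral population, under which most
    derived alleles are rare.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_chrom < 4:
        raise ValueError("n_chrom must be >= 4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    i = np.arange(1, n_chrom)
    w = 1.0 / i
    return rng.choice(i, size=n, p=w / w.sum()) / n_chrom


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """One round of Balding–Nichols drift: Beta draws with mean p, var f·p(1−p).

    Frequencies already fixed at 0 or 1 stay fixed.
    """
    p = np.asarray(p, dtype=float)
    out = p.copy()
    seg = (p > 0) & (p < 1)
    scale = (1.0 - f) / f
    out[seg] = rng.beta(p[seg] * scale, (1.0 - p[seg]) * scale)
    return np.clip(out, 0.0, 1.0)


def simulate_population_frequencies(p0: float, demo: DemographyParams, rng: np.random.Generator) -> dict[str, float]:
    """Drift one ancestral frequency into the five population frequencies.

    AFR drifts directly from p0 with ``f_afr``; an out-of-Africa
    intermediate frequency is drawn with ``f_ooa`` from p0 and each of
    AMR/EAS/EUR/SAS drifts from that intermediate with ``f_pop``.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0={p0} must be in (0,1)")
    m = _simulate_frequency_matrix(np.array([p0]), demo, rng)
    return {pop: float(m[0, k]) for k, pop in enumerate(POPULATIONS)}


def _simulate_frequency_matrix(p0: np.ndarray, demo: DemographyParams, rng: np.random.Generator) -> np.ndarray:
    afr = _balding_nichols(rng, p0, demo.f_afr)
    ooa = _balding_nichols(rng, p0, demo.f_ooa)
    cols = {"AFR": afr}
    for pop in NON_AFRICAN:
        cols[pop] = _balding_nichols(rng, ooa, demo.f_pop)
    return np.column_stack([cols[p] for p in POPULATIONS])


def build_panel(demo: DemographyParams, n_chrom: int = 1000) -> Panel:
    """Generate a synthetic WGS panel under the bottleneck drift model."""
    rng = np.random.default_rng(demo.seed)
    p0 = sample_ancestral_frequency(demo.n_snps, n_chrom=n_chrom, seed=rng)
    daf = _simulate_frequency_matrix(p0, demo, rng)
    n = demo.n_snps
    aa_idx = rng.integers(0, 4, size=n)
    da_idx = (aa_idx + rng.integers(1, 4, size=n)) % 4
    df = pd.DataFrame(
        {
            "id": [f"snp{i:07d}" for i in range(n)],
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 1000,
            "aa": _BASES[aa_idx],
            "da": _BASES[da_idx],
        }
    )
    for k, col in enumerate(DAF_COLUMNS):
        df[col] = daf[:, k]
    df["platforms"] = [frozenset({"WGS"})] * n
    return Panel(
        df[list(_PANEL_COLUMNS)],
        provenance=(
            f"synthetic bottleneck panel: n_snps={n}, f_afr={demo.f_afr}, "
            f"f_ooa={demo.f_ooa}, f_pop={demo.f_pop}, seed={demo.seed}"
        ),
        meta={"seed": demo.seed},
    )


def array_inclusion_probability(q: np.ndarray | float, n_discovery_chrom: int) -> np.ndarray | float:
    """Probability a SNP is polymorphic in a discovery sample of d chromosomes."""
    q = np.asarray(q, dtype=float)
    d = n_discovery_chrom
    out = 1.0 - q**d - (1.0 - q) ** d
    return out if out.ndim else float(out)


def ascertain_array_subset(
    panel: Panel,
    discovery_pop: str = "EUR",
    n_discovery_chrom: int = 4,
    rng: np.random.Generator | int = 0,
) -> Panel:
    """Emulate small-discovery-panel array ascertainment.

    Each SNP is retained with the probability that it is polymorphic in
    ``n_discovery_chrom`` chromosomes sampled from the discovery
    population, which biases the retained set toward intermediate
    frequencies in that population.  Retained SNPs receive the ``SYNTH``
    platform flag; the panel keeps all records.
    """
    if n_discovery_chrom < 2:
        raise ValueError("n_discovery_chrom must be >= 2")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    q = panel.daf(discovery_pop)
    keep = rng.random(len(panel)) < array_inclusion_probability(q, n_discovery_chrom)
    df = panel.df.copy()
    df["platforms"] = [p | {"SYNTH"} if k else p for p, k in zip(df["platforms"], keep)]
    return panel.replace(
        df,
        note=f"SYNTH ascertainment in {discovery_pop}, d={n_discovery_chrom} ({int(keep.sum())} retained)",
        synth_retained=int(keep.sum()),
    )


def simulate_genotypes(
    panel: Panel,
    n_per_pop: Mapping[str, int],
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Hardy–Weinberg diploid genotypes for each population.

    Returns a DataFrame with one row per individual: a ``population``
    column plus one integer column per panel SNP holding the
    derived-allele count (0/1/2), drawn Binomial(2, daf).
    """
    if any(n < 1 for n in n_per_pop.values()):
        raise ValueError("n_per_pop entries must be positive")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    blocks = []
    for pop in POPULATIONS:
        n = n_per_pop.get(pop, 0)
        if n == 0:
            continue
        g = rng.binomial(2, panel.daf(pop)[None, :].repeat(n, axis=0))
        block = pd.DataFrame(g, columns=panel.ids.tolist())
        block.insert(0, "population", pop)
        block.index = [f"{pop}_{i:04d}" for i in range(n)]
        blocks.append(block)
    out = pd.concat(blocks)
    out.index.name = "individual"
    return out


def synthesize_disease_table(
    panel: Panel,
    n_loci: int = 3036,
    prop_ancestral: float = 0.44,
    category_weights: Sequence[float] | None = None,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Draw a disease-locus table from a panel.

    ``n_loci`` distinct variants are sampled uniformly; each risk allele
    is ancestral with probability ``prop_ancestral`` (default 0.44, the
    share of known disease loci with ancestral risk alleles) and
    assigned one of the seven disease categories multinomially.
    """
    if n_loci > len(panel):
        raise ValueError(f"n_loci={n_loci} exceeds panel size {len(panel)}")
    if not 0.0 <= prop_ancestral <= 1.0:
        raise ValueError("prop_ancestral must be in [0,1]")
    if category_weights is None:
        category_weights = np.full(len(CATEGORIES), 1.0 / len(CATEGORIES))
    w = np.asarray(category_weights, dtype=float)
    if len(w) != len(CATEGORIES) or not np.isclose(w.sum(), 1.0):
        raise ValueError("category_weights must be a 7-vector summing to 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    idx = rng.choice(len(panel), size=n_loci, replace=False)
    states = np.where(rng.random(n_loci) < prop_ancestral, "ancestral", "derived")
    cats = rng.choice(len(CATEGORIES), size=n_loci, p=w)
    return pd.DataFrame(
        {
            "id": panel.ids.iloc[idx].to_numpy(),
            "risk_state": states,
            "category": [CATEGORIES[c] for c in cats],
        }
    )


def write_disease_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_disease_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "risk_state", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"disease table missing columns {sorted(missing)}")
    return df


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t")


def read_genotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="individual")
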