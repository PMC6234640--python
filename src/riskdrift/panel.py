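"""Multi-population allele-frequency panels.

A panel holds one row per biallelic SNP with an assigned ancestral and
derived allele and the derived-allele frequency (DAF) in each of the five
continental populations of a global reference cohort (AFR, AMR, EAS, EUR,
SAS).  Panels are read from VCF (using the ``AA`` ancestral-allele INFO
tag) or from a plain tab-separated exchange format, can be intersected
with genotyping-array SNP-ID lists, masked by genomic region, and
summarised as joint site frequency spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Continental population labels, in canonical order.
POPULATIONS: tuple[str, ...] = ("AFR", "AMR", "EAS", "EUR", "SAS")

#: The four non-African populations (pooled in many summaries).
NON_AFRICAN: tuple[str, ...] = ("AMR", "EAS", "EUR", "SAS")

#: Recognised genotyping-platform flags.  WGS is set on every record;
#: AFFY6 / OMNI5 mark commercial array content; SYNTH marks records
#: retained by the synthetic small-panel ascertainment model.
PLATFORMS: tuple[str, ...] = ("WGS", "AFFY6", "OMNI5", "SYNTH")

DAF_COLUMNS: tuple[str, ...] = tuple(f"daf_{p}" for p in POPULATIONS)

_PANEL_COLUMNS = ("id", "chrom", "pos", "aa", "da") + DAF_COLUMNS + ("platforms",)

_BASES = frozenset("ACGT")


def _norm_chrom(chrom: str) -> str:
    """Normalise a chromosome name by stripping any leading 'chr'."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class RegionMask:
    """A 1-based inclusive genomic interval to exclude from a panel."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"mask start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return _norm_chrom(chrom) == _norm_chrom(self.chrom) and self.start <= pos <= self.end


#: Region of chromosome 8 (hg19) where reference ancestral states are
#: unreliable (systematically elevated DAF in every population); masked
#: by default when building empirical panels.
CHR8_MASK = RegionMask("8", 89_000_000, 146_364_022)


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP with ancestral/derived alleles and per-population DAF."""

    id: str
    chrom: str
    pos: int
    ancestral_allele: str
    derived_allele: str
    daf: Mapping[str, float]
    platforms: frozenset[str] = frozenset({"WGS"})

    def __post_init__(self) -> None:
        if self.ancestral_allele not in _BASES or self.derived_allele not in _BASES:
            raise ValueError(f"{self.id}: alleles must be one of A,C,G,T")
        if self.ancestral_allele == self.derived_allele:
            raise ValueError(f"{self.id}: ancestral and derived alleles are identical")
        missing = set(POPULATIONS) - set(self.daf)
        if missing:
            raise ValueError(f"{self.id}: missing DAF for populations {sorted(missing)}")
        for pop, f in self.daf.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.id}: daf[{pop}]={f} outside [0,1]")
        if "WGS" not in self.platforms:
            object.__setattr__(self, "platforms", frozenset(self.platforms) | {"WGS"})


class Panel:
    """An ordered collection of :class:`VariantRecord` backed by a DataFrame.

    Parameters
    ----------
    df
        Columns ``id chrom pos aa da daf_AFR..daf_SAS platforms``; the
        ``platforms`` column holds per-row frozensets of platform flags.
    provenance
        Free-text note on where the panel came from and what filters
        were applied.
    meta
        Machine-readable counters (dropped sites, unmatched array IDs...).
    """

    def __init__(self, df: pd.DataFrame, provenance: str = "", meta: dict | None = None):
        missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel frame missing columns {missing}")
        df = df.loc[:, list(_PANEL_COLUMNS)].reset_index(drop=True)
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].head().tolist()
            raise ValueError(f"duplicate SNP ids in panel (e.g. {dups})")
        daf = df[list(DAF_COLUMNS)].to_numpy(dtype=float)
        if daf.size and (np.nanmin(daf) < 0 or np.nanmax(daf) > 1):
            raise ValueError("DAF values outside [0,1]")
        df["platforms"] = [frozenset(p) | {"WGS"} for p in df["platforms"]]
        self.df = df
        self.provenance = provenance
        self.meta = dict(meta or {})

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[VariantRecord]:
        return self.records()

    def records(self) -> Iterator[VariantRecord]:
        for row in self.df.itertuples(index=False):
            yield VariantRecord(
                id=row.id,
                chrom=row.chrom,
                pos=int(row.pos),
                ancestral_allele=row.aa,
                derived_allele=row.da,
                daf={p: getattr(row, f"daf_{p}") for p in POPULATIONS},
                platforms=row.platforms,
            )

    @property
    def ids(self) -> pd.Series:
        return self.df["id"]

    # -- frequency access ---------------------------------------------------
    def daf(self, population: str) -> np.ndarray:
        if population not in POPULATIONS:
            raise KeyError(f"unknown population {population!r}")
        return self.df[f"daf_{population}"].to_numpy(dtype=float)

    def daf_matrix(self) -> np.ndarray:
        """(n_snps, 5) DAF matrix, columns in :data:`POPULATIONS` order."""
        return self.df[list(DAF_COLUMNS)].to_numpy(dtype=float)

    def platform_mask(self, platform: str) -> np.ndarray:
        if platform not in PLATFORMS:
            raise KeyError(f"unknown platform {platform!r}")
        return np.fromiter((platform in p for p in self.df["platforms"]), dtype=bool, count=len(self.df))

    # -- construction -------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[VariantRecord], provenance: str = "") -> "Panel":
        rows = []
        for r in records:
            row = {"id": r.id, "chrom": r.chrom, "pos": r.pos, "aa": r.ancestral_allele, "da": r.derived_allele}
            row.update({f"daf_{p}": float(r.daf[p]) for p in POPULATIONS})
            row["platforms"] = frozenset(r.platforms)
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(_PANEL_COLUMNS))
        return cls(df, provenance=provenance)

    def replace(self, df: pd.DataFrame, note: str | None = None, **meta) -> "Panel":
        prov = self.provenance if note is None else f"{self.provenance}; {note}".strip("; ")
        merged = {**self.meta, **meta}
        return Panel(df, provenance=prov, meta=merged)

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["platforms"] = [",".join(sorted(p)) for p in out["platforms"]]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Panel":
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str},
                         float_precision="round_trip")
        df["platforms"] = [frozenset(str(p).split(",")) for p in df["platforms"]]
        return cls(df, provenance=f"read from {path}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_vcf_frequencies(vcf_path: str | Path, population_assignment: Mapping[str, str]) -> Panel:
    """Build a panel from a VCF with per-site ancestral-allele annotation.

    Retains biallelic SNPs whose ``AA`` INFO tag (EPO-style; compared
    case-insensitively, extra subfields after ``|`` ignored) matches REF
    or ALT; per-population DAF is the derived-allele count over called
    chromosomes.  Sites with unknown or mismatching ancestral states are
    dropped and counted in ``panel.meta``.

    Raises
    ------
    ValueError
        If any VCF sample lacks a population assignment, or an
        assignment is not one of the five continental populations.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unassigned = [s for s in samples if s not in population_assignment]
    if unassigned:
        raise ValueError(f"samples without population assignment: {unassigned}")
    bad = {s: population_assignment[s] for s in samples if population_assignment[s] not in POPULATIONS}
    if bad:
        raise ValueError(f"unknown population labels: {bad}")

    pop_of_sample = np.array([POPULATIONS.index(population_assignment[s]) for s in samples])
    rows = []
    n_dropped_aa = 0
    n_dropped_nonbiallelic = 0
    for v in vcf:
        ref, alts = v.REF, v.ALT
        if len(alts) != 1 or ref not in _BASES or alts[0] not in _BASES:
            n_dropped_nonbiallelic += 1
            continue
        alt = alts[0]
        aa_raw = v.INFO.get("AA")
        aa = str(aa_raw).split("|")[0].strip().upper() if aa_raw is not None else ""
        if aa not in _BASES or aa not in (ref, alt):
            n_dropped_aa += 1
            continue
        derived = alt if aa == ref else ref
        # genotype array: (n_samples, ploidy+1); last column is phasing
        gts = np.array(v.genotypes, dtype=int)[:, :2]
        daf = {}
        ok = True
        for k, pop in enumerate(POPULATIONS):
            g = gts[pop_of_sample == k]
            called = g >= 0
            n_chrom = int(called.sum())
            if n_chrom == 0:
                ok = False
                break
            alt_count = int(g[called].sum())
            freq = alt_count / n_chrom
            daf[pop] = freq if derived == alt else 1.0 - freq
        if not ok:
            n_dropped_aa += 1
            continue
        snp_id = v.ID if v.ID else f"{v.CHROM}:{v.POS}"
        row = {"id": snp_id, "chrom": _norm_chrom(v.CHROM), "pos": v.POS, "aa": aa, "da": derived}
        row.update({f"daf_{p}": daf[p] for p in POPULATIONS})
        row["platforms"] = frozenset({"WGS"})
        rows.append(row)

    if n_dropped_aa:
        logger.info("dropped %d sites with unknown/mismatching ancestral allele", n_dropped_aa)
    df = pd.DataFrame(rows, columns=list(_PANEL_COLUMNS))
    return Panel(
        df,
        provenance=f"read_vcf_frequencies({vcf_path}); dropped_aa={n_dropped_aa}",
        meta={"dropped_aa": n_dropped_aa, "dropped_nonbiallelic": n_dropped_nonbiallelic},
    )


def apply_region_mask(panel: Panel, mask: RegionMask = CHR8_MASK) -> Panel:
    """Remove records inside a 1-based inclusive genomic interval."""
    chrom = panel.df["chrom"].map(_norm_chrom)
    pos = panel.df["pos"]
    inside = (chrom == _norm_chrom(mask.chrom)) & (pos >= mask.start) & (pos <= mask.end)
    n_removed = int(inside.sum())
    out = panel.df.loc[~inside]
    return panel.replace(out, note=f"masked {mask.chrom}:{mask.start}-{mask.end} ({n_removed} removed)",
                         masked_out=n_removed)


def load_array_snp_ids(path: str | Path, platform: str, panel: Panel) -> Panel:
    """Flag panel records present on a genotyping array (one SNP ID per line).

    IDs in the list that are absent from the panel are counted in
    ``panel.meta['unmatched_<platform>']``; flagging is idempotent.
    """
    if platform not in ("AFFY6", "OMNI5", "SYNTH"):
        raise ValueError(f"platform must be an array platform, got {platform!r}")
    ids = {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}
    if not ids:
        raise ValueError(f"SNP-ID list {path} is empty")
    present = panel.df["id"].isin(ids)
    n_unmatched = len(ids) - int(present.sum())
    if n_unmatched:
        logger.info("%d %s list IDs not in panel", n_unmatched, platform)
    df = panel.df.copy()
    df["platforms"] = [
        p | {platform} if hit else p for p, hit in zip(df["platforms"], present)
    ]
    return panel.replace(df, note=f"{platform} flags from {path} ({n_unmatched} unmatched)",
                         **{f"unmatched_{platform}": n_unmatched})


def joint_sfs_counts(panel: Panel, pop_x: str, pop_y: str, bins: int = 10) -> np.ndarray:
    """Joint site frequency spectrum of two populations as a bins×bins count matrix.

    A record falls in cell ``(floor(daf_x*bins), floor(daf_y*bins))``;
    frequency 1.0 is assigned to the top bin.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    ix = np.minimum((panel.daf(pop_x) * bins).astype(int), bins - 1)
    iy = np.minimum((panel.daf(pop_y) * bins).astype(int), bins - 1)
    m = np.zeros((bins, bins), dtype=int)
    np.add.at(m, (ix, iy), 1)
    return m


def pooled_nonafrican_daf(record: VariantRecord, chrom_counts: Mapping[str, int] | None = None) -> float:
    """Pooled non-African derived-allele frequency of one record.

    By default the unweighted mean over AMR/EAS/EUR/SAS; passing
    per-population chromosome counts switches to a chromosome-count
    weighted pool.
    """
    freqs = np.array([record.daf[p] for p in NON_AFRICAN], dtype=float)
    if chrom_counts is None:
        return float(freqs.mean())
    w = np.array([chrom_counts[p] for p in NON_AFRICAN], dtype=float)
    return float(np.average(freqs, weights=w))


def pooled_nonafrican_daf_array(panel: Panel) -> np.ndarray:
    """Per-record unweighted mean DAF over the four non-African populations."""
    return panel.df[[f"daf_{p}" for p in NON_AFRICAN]].to_numpy(dtype=float).mean(axis=1)
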