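"""Readers/writers, genotype QC, and SNP/gene/pathway annotation.

Conventions
-----------
* Genotypes are stored as minor-allele dosages in {0, 1, 2} with ``-1`` as
  the missing code.  The minor allele is determined per SNP from the full
  sample set; ties at MAF = 0.5 break to ``allele2``.
* Genomic coordinates are 1-based, fully closed intervals (PLINK/BIM
  convention); gene windows are boundary-inclusive.  Strand is ignored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

MISSING = -1

VALID_ALLELES = frozenset("ACGT0")


@dataclass
class GenotypeStudy:
    """Case/control genotype matrix with SNP coordinates.

    Attributes
    ----------
    dosage : (n_samples, n_snps) int8 array
        Minor-allele counts in {0, 1, 2}; ``-1`` marks a missing genotype.
    phenotype : (n_samples,) int array
        1 = case, 0 = control.
    sample_ids : list of str
    snp_table : DataFrame with columns id, chrom, pos, a1, a2
        ``a2`` is the minor (counted) allele.
    """

    dosage: np.ndarray
    phenotype: np.ndarray
    sample_ids: list[str]
    snp_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int64)
        if self.dosage.shape != (len(self.phenotype), len(self.snp_table)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.phenotype)} samples x {len(self.snp_table)} SNPs"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2} or missing (-1)")
        if not self.snp_table["id"].is_unique:
            raise ValueError("SNP ids must be unique")
        if (self.snp_table["pos"] < 0).any():
            raise ValueError("SNP positions must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_table["id"].to_numpy()

    def snp_index(self, snp_ids) -> np.ndarray:
        """Column indices for the given SNP ids (order preserved)."""
        lookup = pd.Index(self.snp_table["id"])
        idx = lookup.get_indexer(list(snp_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"unknown SNP ids: {missing[:5]}")
        return idx

    def subset_snps(self, keep: np.ndarray) -> "GenotypeStudy":
        """New study restricted to the SNP columns selected by ``keep``."""
        return GenotypeStudy(
            dosage=self.dosage[:, keep],
            phenotype=self.phenotype.copy(),
            sample_ids=list(self.sample_ids),
            snp_table=self.snp_table.iloc[np.atleast_1d(keep)].reset_index(drop=True),
        )

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP over non-missing genotypes."""
        obs = self.dosage != MISSING
        counts = np.where(obs, self.dosage, 0).sum(axis=0)
        denom = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)

    def call_rate(self) -> np.ndarray:
        return (self.dosage != MISSING).mean(axis=0)


@dataclass
class GeneSetCollection:
    """Mapping pathway id -> set of gene symbols, with a source tag each."""

    sets: dict[str, frozenset[str]]
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.source.setdefault(name, _infer_source(name))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def size_filtered(self, min_size: int = 1, max_size: int = 500) -> "GeneSetCollection":
        kept = {k: v for k, v in self.sets.items() if min_size <= len(v) <= max_size}
        return GeneSetCollection(kept, {k: self.source[k] for k in kept})

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


def _infer_source(name: str) -> str:
    upper = name.upper()
    for tag in ("KEGG", "BIOCARTA", "REACTOME", "GO"):
        if upper.startswith(tag):
            return tag
    return "UNKNOWN"


@dataclass
class QCConfig:
    """Thresholds for SNP quality control.

    Defaults mirror common GWAS practice: call rate >= 90%, MAF >= 1%,
    Hardy-Weinberg exact p >= 1e-4 computed in controls.
    """

    min_call_rate: float = 0.90
    min_maf: float = 0.01
    hwe_p_threshold: float = 1e-4
    hwe_in_controls_only: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_p_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> GeneSetCollection:
    """Read an MSigDB-style GMT file (name, description, genes...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = genes
    if not sets:
        raise ValueError(f"{path}: no gene sets")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, collection.source.get(name, "na"), *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# PLINK text .ped/.map and the TSV dosage dialect


def read_genotypes(ped_path, map_path) -> GenotypeStudy:
    """Read PLINK text .ped/.map into minor-allele dosages.

    Phenotype column 6 follows PLINK coding: 1 = control, 2 = case; any
    other value drops the sample with a warning.  Missing genotype "0 0".
    """
    snp_table = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos"],
        dtype={"chrom": str, "id": str},
    )
    n_snps = len(snp_table)
    sample_ids: list[str] = []
    phenos: list[int] = []
    rows: list[np.ndarray] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields, got {len(fields)}"
                )
            pheno_code = fields[5]
            if pheno_code not in ("1", "2"):
                warnings.warn(
                    f"{ped_path}:{lineno}: sample {fields[1]} has unknown phenotype "
                    f"{pheno_code!r}; excluded"
                )
                continue
            pair_list = []
            for j in range(n_snps):
                a, b = fields[6 + 2 * j], fields[7 + 2 * j]
                if a not in VALID_ALLELES or b not in VALID_ALLELES:
                    raise ValueError(
                        f"{ped_path}:{lineno}: invalid allele symbol {a!r}/{b!r} at SNP {j}"
                    )
                pair_list.append((a, b))
            allele_rows.append(pair_list)
            sample_ids.append(fields[1])
            phenos.append(1 if pheno_code == "2" else 0)
    if not sample_ids:
        raise ValueError("no samples with known phenotype")

    dosage = np.full((len(sample_ids), n_snps), MISSING, dtype=np.int8)
    a1_col, a2_col = [], []
    for j in range(n_snps):
        counts: dict[str, int] = {}
        for i in range(len(sample_ids)):
            for al in allele_rows[i][j]:
                if al != "0":
                    counts[al] = counts.get(al, 0) + 1
        alleles = sorted(counts, key=lambda a: (counts[a], a))
        if not alleles:
            minor, major = "0", "0"
        elif len(alleles) == 1:
            major, minor = alleles[0], "0"
        else:
            # ascending count: first is rarest; tie at 0.5 -> later sort key
            a_lo, a_hi = alleles[0], alleles[-1]
            if counts[a_lo] == counts[a_hi]:
                # tie: allele2 slot (lexicographically later) is minor
                major, minor = sorted((a_lo, a_hi))
            else:
                minor, major = a_lo, a_hi
        a1_col.append(major)
        a2_col.append(minor)
        for i in range(len(sample_ids)):
            a, b = allele_rows[i][j]
            if a == "0" or b == "0":
                continue
            dosage[i, j] = int(a == minor) + int(b == minor)

    snp_table = pd.DataFrame(
        {
            "id": snp_table["id"],
            "chrom": snp_table["chrom"],
            "pos": snp_table["pos"].astype(np.int64),
            "a1": a1_col,
            "a2": a2_col,
        }
    )
    return GenotypeStudy(dosage, np.array(phenos), sample_ids, snp_table)


def write_genotypes(study: GenotypeStudy, ped_path, map_path) -> None:
    """Write PLINK text .ped/.map (inverse of :func:`read_genotypes`)."""
    with open(map_path, "w") as fh:
        for rec in study.snp_table.itertuples():
            fh.write(f"{rec.chrom}\t{rec.id}\t0\t{rec.pos}\n")
    a1 = study.snp_table["a1"].to_numpy()
    a2 = study.snp_table["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(study.sample_ids):
            fields = [sid, sid, "0", "0", "0", "2" if study.phenotype[i] == 1 else "1"]
            for j in range(study.n_snps):
                d = study.dosage[i, j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


def read_dosage_tsv(dosage_path, snp_path) -> GenotypeStudy:
    """Read the TSV dosage dialect.

    ``dosage_path``: header ``sample_id<TAB>phenotype<TAB><snp ids...>``;
    dosages are integers with -1 for missing; phenotype in {0, 1}.
    ``snp_path``: sidecar with columns id, chrom, pos, a1, a2.
    """
    df = pd.read_csv(dosage_path, sep="\t", dtype={"sample_id": str})
    snp_table = pd.read_csv(snp_path, sep="\t", dtype={"id": str, "chrom": str})
    snp_cols = [c for c in df.columns if c not in ("sample_id", "phenotype")]
    if list(snp_table["id"]) != snp_cols:
        raise ValueError("SNP sidecar order does not match dosage columns")
    return GenotypeStudy(
        dosage=df[snp_cols].to_numpy(dtype=np.int8),
        phenotype=df["phenotype"].to_numpy(dtype=np.int64),
        sample_ids=list(df["sample_id"]),
        snp_table=snp_table.reset_index(drop=True),
    )


def write_dosage_tsv(study: GenotypeStudy, dosage_path, snp_path) -> None:
    df = pd.DataFrame(study.dosage, columns=study.snp_table["id"])
    df.insert(0, "phenotype", study.phenotype)
    df.insert(0, "sample_id", study.sample_ids)
    df.to_csv(dosage_path, sep="\t", index=False)
    study.snp_table.to_csv(snp_path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    """4-column gene TSV: symbol, chrom, start, end (1-based closed)."""
    genes = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chrom": str})
    return validate_gene_table(genes)


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    required = {"symbol", "chrom", "start", "end"}
    if not required <= set(genes.columns):
        raise ValueError(f"gene table must have columns {sorted(required)}")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene table has start > end")
    if not genes["symbol"].is_unique:
        raise ValueError("gene symbols must be unique")
    return genes


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Wigginton-style enumeration)


def hwe_exact_p(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Enumerates all heterozygote counts compatible with the observed allele
    totals and sums the conditional probabilities of configurations no more
    probable than the observed one.
    """
    if min(n_het, n_hom_rare, n_hom_common) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    n_rare = 2 * n_hom_rare + n_het
    # work with the rarer allele
    if n_rare > n:
        n_rare = 2 * n - n_rare
    # heterozygote count has the parity of n_rare
    het_values = range(n_rare % 2, n_rare + 1, 2)
    log_probs = []
    for h in het_values:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        if hom_c < 0:
            continue
        lp = (
            h * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_r + 1)
            - math.lgamma(hom_c + 1)
            + math.lgamma(n_rare + 1)
            + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )
        log_probs.append((h, lp))
    m = max(lp for _, lp in log_probs)
    probs = {h: math.exp(lp - m) for h, lp in log_probs}
    total = sum(probs.values())
    obs = probs.get(n_het)
    if obs is None:  # inconsistent counts cannot occur for valid input
        raise ValueError("observed heterozygote count incompatible with allele totals")
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def qc_filter(study: GenotypeStudy, cfg: QCConfig | None = None):
    """Remove SNPs failing call-rate, MAF, or HWE-exact filters.

    Returns ``(filtered_study, removal_counts)`` where the counts record,
    per filter, how many SNPs it flagged (a SNP may fail several filters).
    """
    cfg = cfg or QCConfig()
    call = study.call_rate()
    maf = study.maf()
    fail_call = call < cfg.min_call_rate
    fail_maf = np.nan_to_num(maf, nan=0.0) < cfg.min_maf

    if cfg.hwe_in_controls_only:
        mask = study.phenotype == 0
    else:
        mask = np.ones(study.n_samples, dtype=bool)
    dos = study.dosage[mask]
    fail_hwe = np.zeros(study.n_snps, dtype=bool)
    for j in range(study.n_snps):
        col = dos[:, j]
        col = col[col != MISSING]
        n_het = int((col == 1).sum())
        n_hom_rare = int((col == 2).sum())
        n_hom_common = int((col == 0).sum())
        if hwe_exact_p(n_het, n_hom_rare, n_hom_common) < cfg.hwe_p_threshold:
            fail_hwe[j] = True

    keep = ~(fail_call | fail_maf | fail_hwe)
    if not keep.any():
        raise ValueError("empty study after QC")
    counts = {
        "call_rate": int(fail_call.sum()),
        "maf": int(fail_maf.sum()),
        "hwe": int(fail_hwe.sum()),
        "removed": int((~keep).sum()),
        "kept": int(keep.sum()),
    }
    return study.subset_snps(np.where(keep)[0]), counts


# ---------------------------------------------------------------------------
# SNP -> gene annotation


def map_snps_to_genes(
    snp_table: pd.DataFrame, genes: pd.DataFrame, window_kb: float = 20.0
) -> dict[str, list[str]]:
    """Assign each SNP to every gene whose windowed interval contains it.

    The window extends ``window_kb`` kilobases beyond both gene ends,
    boundary-inclusive; a SNP inside several overlapping windows is assigned
    to all of them.  Genes with no SNPs are omitted.
    """
    window = int(round(window_kb * 1000))
    out: dict[str, list[str]] = {}
    snp_by_chrom = {
        chrom: grp.sort_values("pos") for chrom, grp in snp_table.groupby("chrom")
    }
    for rec in genes.itertuples():
        grp = snp_by_chrom.get(rec.chrom)
        if grp is None:
            continue
        lo, hi = rec.start - window, rec.end + window
        pos = grp["pos"].to_numpy()
        i0, i1 = np.searchsorted(pos, lo, "left"), np.searchsorted(pos, hi, "right")
        if i1 > i0:
            out[rec.symbol] = list(grp["id"].iloc[i0:i1])
    return out


def sets_to_snp_map(
    sets: GeneSetCollection, gene_snp_map: dict[str, list[str]]
) -> dict[str, list[str]]:
    """Union per pathway of its member genes' SNPs (duplicates removed)."""
    out: dict[str, list[str]] = {}
    for name, genes in sets.items():
        snps: dict[str, None] = {}
        for g in sorted(genes):
            for s in gene_snp_map.get(g, ()):
                snps[s] = None
        if snps:
            out[name] = list(snps)
    return out


# ---------------------------------------------------------------------------
# Network export


def log005(p) -> np.ndarray:
    """log base 0.05 of p: ln(p)/ln(0.05); 1 at p = 0.05, 0 at p = 1."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return np.log(p) / np.log(0.05)


def export_network(
    pathway_stats: dict[str, float],
    gene_stats: dict[str, float],
    membership: dict[str, list[str] | frozenset[str]],
    edge_path,
    node_path,
) -> None:
    """Write a pathway-gene edge list and a node table weighted by log005(p)."""
    edges = []
    for pw, genes in membership.items():
        for g in sorted(genes):
            if g in gene_stats:
                edges.append((pw, g))
    pd.DataFrame(edges, columns=["source", "target"]).to_csv(edge_path, sep="\t", index=False)
    nodes = [
        (name, "pathway", float(log005(p))) for name, p in pathway_stats.items()
    ] + [(name, "gene", float(log005(p))) for name, p in gene_stats.items()]
    pd.DataFrame(nodes, columns=["node", "kind", "weight"]).to_csv(
        node_path, sep="\t", index=False
    )
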