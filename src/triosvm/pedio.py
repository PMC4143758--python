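"""Linkage-format (PED/MAP) pedigree I/O, trio extraction and rare-site selection.

The sampling unit downstream is the parent-child trio: a phenotyped child
whose two parents are both genotyped.  Trios are extracted from arbitrary
pedigrees and treated as independent, even when they share parents or belong
to the same extended pedigree.  In deep pedigrees linkage disequilibrium
extends much further than in unrelated samples, so significant results can be
driven by rare alleles hitch-hiking on a causal haplotype in a nearby gene;
callers analysing multigenerational data should interpret small p-values with
that caveat in mind.

Genotypes are stored as rare-allele counts in {0, 1, 2}, ``MISSING`` (= -1)
for unknown.  Sites are oriented so the counted allele is the minor allele in
founders; at exactly 0.5 the lexicographically larger allele is counted, which
makes orientation (and hence the PED round-trip) deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: genotype code for a missing (unknown) allele pair
MISSING: int = -1

_SAMPLE_COLUMNS = [
    "family_id",
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "affection",
]

# linkage phenotype codes: 2 = affected, 1 = unaffected, 0 / -9 = missing
_PHENO_CODES = {"2": True, "1": False, "0": None, "-9": None}


class PedFormatError(ValueError):
    """Malformed PED/MAP input; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass
class VariantSite:
    """A biallelic site with its minor-allele ('rare') orientation.

    ``maf`` is filled in by :func:`compute_maf`; ``None`` means not yet
    computed and ``nan`` means undefined (all genotypes missing).
    """

    site_id: str
    chromosome: str
    position_bp: int
    allele_ref: str = "A"
    allele_rare: str = "a"
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"position_bp must be >= 1, got {self.position_bp}")
        if self.allele_ref == self.allele_rare:
            raise ValueError("reference and rare allele must differ")


@dataclass
class GeneRegion:
    """A gene analysis unit: 1-based inclusive coordinates on one chromosome."""

    gene: str
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp < 1 or self.end_bp < self.start_bp:
            raise ValueError(
                f"invalid region {self.gene}: [{self.start_bp}, {self.end_bp}]"
            )


@dataclass
class Trio:
    """A child with both parental genotype vectors and an affection label."""

    child_id: str
    father_id: str
    mother_id: str
    child_g: np.ndarray
    father_g: np.ndarray
    mother_g: np.ndarray
    affected: bool

    def __post_init__(self) -> None:
        if not (len(self.child_g) == len(self.father_g) == len(self.mother_g)):
            raise ValueError("trio genotype vectors must share length and site order")

    @property
    def label(self) -> int:
        """SVM vertex: -1 for an affected child, +1 otherwise."""
        return -1 if self.affected else +1


@dataclass
class GenotypeTable:
    """Samples x sites matrix of rare-allele counts with pedigree metadata.

    ``samples`` holds family_id, individual_id, father_id, mother_id, sex and
    affection (True / False / None); ``genotypes`` is int8 with entries in
    {0, 1, 2, MISSING}.
    """

    samples: pd.DataFrame
    sites: list[VariantSite]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        ok = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("genotype entries must be in {0, 1, 2} or missing")
        missing_cols = [c for c in _SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValueError(f"samples frame lacks columns {missing_cols}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def founder_mask(self) -> np.ndarray:
        """Founders are individuals with neither parent listed in the file."""
        s = self.samples
        return ((s["father_id"] == "0") & (s["mother_id"] == "0")).to_numpy()


# ---------------------------------------------------------------------------
# reading / writing


def _read_map(map_path) -> list[tuple[str, str, int]]:
    entries: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) not in (3, 4):
                raise PedFormatError(
                    f"MAP rows need 3 or 4 fields, got {len(tok)}", lineno
                )
            try:
                pos = int(tok[-1])
            except ValueError as exc:
                raise PedFormatError(f"bad position {tok[-1]!r}", lineno) from exc
            entries.append((tok[0], tok[1], pos))
    if not entries:
        raise PedFormatError(f"empty MAP file {map_path}")
    return entries


def read_ped(ped_path, map_path) -> GenotypeTable:
    """Read linkage-format PED + MAP into a minor-allele-oriented table.

    Unknown alleles ('0') become missing genotypes.  Sites with more than two
    observed alleles are dropped with a warning (the method is defined for
    biallelic counts).  Counts are oriented to the minor allele in founders
    (all samples when the file has no founders).
    """
    map_entries = _read_map(map_path)
    m = len(map_entries)

    meta_rows: list[list[str]] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise PedFormatError(
                    f"expected {6 + 2 * m} fields for {m} sites, got {len(tok)}",
                    lineno,
                )
            meta_rows.append(tok[:6])
            allele_rows.append(tok[6:])
    if not meta_rows:
        raise PedFormatError(f"empty PED file {ped_path}")

    n = len(meta_rows)
    meta = pd.DataFrame(
        meta_rows,
        columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "pheno"],
    )
    affection = meta["pheno"].map(lambda c: _PHENO_CODES.get(c, None))
    samples = meta.drop(columns="pheno").assign(affection=affection)
    alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2)

    founders = ((samples["father_id"] == "0") & (samples["mother_id"] == "0")).to_numpy()
    orient_rows = founders if founders.any() else np.ones(n, bool)

    sites: list[VariantSite] = []
    cols: list[np.ndarray] = []
    for j, (chrom, sid, pos) in enumerate(map_entries):
        a = alleles[:, j, :]
        observed = sorted({x for x in a.ravel() if x != "0"})
        if len(observed) > 2:
            log.warning(
                "site %s has %d alleles (%s); dropped (biallelic sites only)",
                sid, len(observed), ",".join(observed),
            )
            continue
        miss = (a[:, 0] == "0") | (a[:, 1] == "0")
        if not observed:  # every genotype missing
            g = np.full(n, MISSING, dtype=np.int8)
            sites.append(VariantSite(sid, chrom, pos, "N", "."))
            cols.append(g)
            continue
        counted = observed[-1]  # lexicographically larger allele first
        other = observed[0] if len(observed) == 2 else "."
        g = ((a[:, 0] == counted).astype(np.int8) + (a[:, 1] == counted).astype(np.int8))
        g[miss] = MISSING
        sel = g[orient_rows]
        sel = sel[sel != MISSING]
        if sel.size == 0:  # founders untyped here; orient on everyone
            sel = g[g != MISSING]
        freq = float(sel.sum()) / (2.0 * sel.size)
        if freq > 0.5:  # counted allele is the major one: flip
            g = np.where(g == MISSING, MISSING, 2 - g).astype(np.int8)
            ref, rare = counted, other
        else:
            ref, rare = other, counted
        sites.append(VariantSite(sid, chrom, pos, ref, rare))
        cols.append(g)

    if not sites:
        raise PedFormatError("no usable biallelic sites in input")
    genotypes = np.column_stack(cols)
    return GenotypeTable(samples=samples, sites=sites, genotypes=genotypes)


def write_ped(table: GenotypeTable, ped_path, map_path) -> None:
    """Write a table back to linkage format (inverse of :func:`read_ped`)."""
    with open(map_path, "w") as fh:
        for s in table.sites:
            fh.write(f"{s.chromosome}\t{s.site_id}\t0\t{s.position_bp}\n")
    pheno = {True: "2", False: "1", None: "0"}
    with open(ped_path, "w") as fh:
        for i, row in enumerate(table.samples.itertuples(index=False)):
            fields = [
                row.family_id,
                row.individual_id,
                row.father_id,
                row.mother_id,
                str(row.sex),
                pheno[row.affection],
            ]
            for j, s in enumerate(table.sites):
                g = table.genotypes[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [s.allele_ref, s.allele_ref]
                elif g == 1:
                    fields += [s.allele_ref, s.allele_rare]
                else:
                    fields += [s.allele_rare, s.allele_rare]
            fh.write(" ".join(fields) + "\n")


def read_regions(path) -> list[GeneRegion]:
    """Read a 4-column TSV of gene regions (gene, chrom, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    aliases = {"chromosome": "chrom", "start_bp": "start", "end_bp": "end"}
    df = df.rename(columns=aliases)
    need = {"gene", "chrom", "start", "end"}
    if not need.issubset(df.columns):
        raise PedFormatError(
            f"regions file needs columns {sorted(need)}, found {list(df.columns)}"
        )
    return [
        GeneRegion(r.gene, r.chrom, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# trio extraction and site selection


def extract_trios(table: GenotypeTable) -> list[Trio]:
    """One Trio per phenotyped child whose two parents are both in the table.

    Children lacking a genotyped parent, or with missing affection, are
    skipped (counted in an INFO log).  Trios are returned in file order and
    treated as independent even when they share parents or pedigrees.
    """
    s = table.samples
    index: dict[tuple[str, str], int] = {}
    for i, (fam, iid) in enumerate(zip(s["family_id"], s["individual_id"])):
        key = (fam, iid)
        if key in index:
            log.warning("duplicate individual %s:%s; keeping first occurrence", fam, iid)
            continue
        index[key] = i

    trios: list[Trio] = []
    n_no_parent = 0
    n_no_pheno = 0
    for i, row in enumerate(s.itertuples(index=False)):
        if row.father_id == "0" or row.mother_id == "0":
            continue
        fi = index.get((row.family_id, row.father_id))
        mi = index.get((row.family_id, row.mother_id))
        if fi is None or mi is None:
            n_no_parent += 1
            continue
        if row.affection is None:
            n_no_pheno += 1
            continue
        trios.append(
            Trio(
                child_id=f"{row.family_id}:{row.individual_id}",
                father_id=f"{row.family_id}:{row.father_id}",
                mother_id=f"{row.family_id}:{row.mother_id}",
                child_g=table.genotypes[i].copy(),
                father_g=table.genotypes[fi].copy(),
                mother_g=table.genotypes[mi].copy(),
                affected=bool(row.affection),
            )
        )
    log.info(
        "extracted %d trios (%d children lacked a genotyped parent, "
        "%d lacked a phenotype)",
        len(trios), n_no_parent, n_no_pheno,
    )
    return trios


def trios_to_table(
    trios: list[Trio],
    chromosome: str = "1",
    positions: list[int] | None = None,
    site_ids: list[str] | None = None,
) -> GenotypeTable:
    """Assemble independent trios into a GenotypeTable (one family per trio).

    The inverse of :func:`extract_trios` for simulated / resampled trios whose
    ids follow the ``family:individual`` convention.  Parents are written as
    founders with missing affection.
    """
    if not trios:
        raise ValueError("no trios to assemble")
    m = len(trios[0].child_g)
    positions = positions or list(range(1, m + 1))
    site_ids = site_ids or [f"s{p}" for p in positions]
    sites = [
        VariantSite(site_ids[j], chromosome, positions[j], "A", "a")
        for j in range(m)
    ]

    rows = []
    geno = []
    seen_fams: set[str] = set()
    for t in trios:
        fam = t.child_id.split(":", 1)[0]
        if fam in seen_fams:
            raise ValueError(f"duplicate family id {fam!r}; re-id trios first")
        seen_fams.add(fam)
        fid = t.father_id.split(":", 1)[1]
        mid = t.mother_id.split(":", 1)[1]
        cid = t.child_id.split(":", 1)[1]
        rows.append((fam, fid, "0", "0", 1, None))
        rows.append((fam, mid, "0", "0", 2, None))
        rows.append((fam, cid, fid, mid, 0, t.affected))
        geno += [t.father_g, t.mother_g, t.child_g]
    samples = pd.DataFrame(rows, columns=_SAMPLE_COLUMNS)
    return GenotypeTable(samples=samples, sites=sites, genotypes=np.stack(geno))


def compute_maf(table: GenotypeTable, founders_only: bool = True) -> np.ndarray:
    """Per-site minor-allele frequency, written onto ``table.sites[j].maf``.

    Founders only by default: transmitted alleles appear in both parent and
    child, so pooling everyone double-counts them.  Columns whose counted
    allele turns out to be the major one (frequency > 0.5) are flipped in
    place, keeping the table minor-allele oriented.  All-missing sites get
    ``nan`` and are never selected downstream.
    """
    if table.n_samples == 0 or table.n_sites == 0:
        raise ValueError("cannot compute MAF on an empty table")
    if founders_only:
        rows = table.founder_mask()
        if not rows.any():
            log.warning("no founders in table; computing MAF over all samples")
            rows = np.ones(table.n_samples, bool)
    else:
        rows = np.ones(table.n_samples, bool)

    out = np.full(table.n_sites, np.nan)
    G = table.genotypes
    for j, site in enumerate(table.sites):
        col = G[rows, j]
        col = col[col != MISSING]
        if col.size == 0:
            site.maf = float("nan")
            continue
        f = float(col.sum()) / (2.0 * col.size)
        if f > 0.5:
            flip = G[:, j] != MISSING
            G[flip, j] = 2 - G[flip, j]
            site.allele_ref, site.allele_rare = site.allele_rare, site.allele_ref
            f = 1.0 - f
        site.maf = f
        out[j] = f
    return out


def select_sites(
    table: GenotypeTable, region: GeneRegion, maf_threshold: float
) -> list[int]:
    """Indices of polymorphic rare sites inside a region, in position order.

    Keeps sites with ``start <= position <= end`` and ``0 < maf < threshold``
    (strict on both sides: monomorphic sites carry no transmission
    information).  An empty result is legal; the gene is then untestable.
    """
    if not 0 < maf_threshold <= 0.5:
        raise ValueError(f"maf_threshold must be in (0, 0.5], got {maf_threshold}")
    picked: list[tuple[int, int]] = []
    for j, s in enumerate(table.sites):
        if s.maf is None:
            raise RuntimeError("site MAFs not computed; call compute_maf first")
        if s.chromosome != region.chromosome:
            continue
        if not region.start_bp <= s.position_bp <= region.end_bp:
            continue
        if np.isnan(s.maf) or not 0.0 < s.maf < maf_threshold:
            continue
        picked.append((s.position_bp, j))
    picked.sort()
    return [j for _, j in picked]
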