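"""Domain types and I/O for the merged variant-call genotype matrix.

A genotype matrix is a loci x samples grid of unordered diploid allele
pairs. Alleles are encoded as small integers:

* ``0`` — the REF allele,
* ``1..k`` — ALT alleles in VCF order (multi-allelic records keep their
  indices),
* ``NULL`` (``-1``) — the imputed dropout ("null") allele. NULL is a real
  allele that participates in genotypes and frequencies; it is distinct
  from MISSING,
* ``MISSING`` (``-9``) — no genotype call at all.

Each genotype additionally carries a provenance flag recording whether it
was observed in the input, imputed with a null allele, recoded during
mother-offspring correction, or blanked as Mendelian-incompatible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# allele codes
NULL = -1
MISSING = -9

# provenance codes
OBSERVED = 0
IMPUTED_NULL = 1
CORRECTED_TO_MISSING = 2
MENDEL_RECODED = 3

PROVENANCE_NAMES = {
    OBSERVED: "observed",
    IMPUTED_NULL: "imputed_null",
    CORRECTED_TO_MISSING: "corrected_to_missing",
    MENDEL_RECODED: "mendel_recoded",
}
PROVENANCE_CODES = {v: k for k, v in PROVENANCE_NAMES.items()}

SPECIES = ("ilex", "suber", "hybrid")
COHORTS = ("adult", "seedling")

NULL_SYMBOL = "<NULL>"


@dataclass(frozen=True)
class Locus:
    """A variant site with its declared alleles and bookkeeping fields."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...] = ()
    total_depth: int | None = None
    region: str = "unassigned"  # exon | intron | intergenic | unassigned
    fragment_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus position must be >= 1, got {self.pos}")
        object.__setattr__(self, "alts", tuple(self.alts))

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def n_alleles(self) -> int:
        """Number of declared non-NULL alleles (REF + ALTs)."""
        return 1 + len(self.alts)

    @property
    def variant_type(self) -> str:
        """``SNP`` iff every allele sequence is a single base, else ``indel``."""
        seqs = (self.ref, *self.alts)
        return "SNP" if all(len(s) == 1 for s in seqs) else "indel"

    def allele_symbol(self, code: int) -> str:
        if code == NULL:
            return NULL_SYMBOL
        if code == 0:
            return self.ref
        return self.alts[code - 1]


@dataclass(frozen=True)
class SampleMeta:
    """Species / cohort / mother assignment of one sample."""

    sample_id: str
    species: str
    cohort: str
    mother_id: str | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r} for {self.sample_id}")
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r} for {self.sample_id}")
        if self.cohort == "seedling" and not self.mother_id:
            raise ValueError(f"seedling {self.sample_id} lacks a mother_id")
        if self.cohort == "adult" and self.mother_id:
            raise ValueError(f"adult {self.sample_id} must not carry a mother_id")


@dataclass
class GenotypeMatrix:
    """Loci x samples genotype grid with provenance flags.

    ``gt`` has shape (n_loci, n_samples, 2) holding sorted allele-code
    pairs; a MISSING genotype is the pair (MISSING, MISSING). ``prov`` has
    shape (n_loci, n_samples) with the provenance codes above.
    """

    loci: list[Locus]
    samples: list[SampleMeta]
    gt: np.ndarray
    prov: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.int16)
        if self.prov is None:
            self.prov = np.zeros(self.gt.shape[:2], dtype=np.int8)
        self.prov = np.asarray(self.prov, dtype=np.int8)
        L, S = len(self.loci), len(self.samples)
        if self.gt.shape != (L, S, 2):
            raise ValueError(f"gt shape {self.gt.shape} != ({L}, {S}, 2)")
        if self.prov.shape != (L, S):
            raise ValueError(f"prov shape {self.prov.shape} != ({L}, {S})")
        self.gt = np.sort(self.gt, axis=2)
        self._validate_alleles()

    def _validate_alleles(self) -> None:
        for i, locus in enumerate(self.loci):
            pair = self.gt[i]
            called = pair[pair[:, 0] != MISSING]
            if called.size and (
                called.min() < NULL or called.max() >= locus.n_alleles
            ):
                raise ValueError(
                    f"genotype at {locus.locus_id} uses an allele code outside "
                    f"[{NULL}, {locus.n_alleles - 1}]"
                )
            half = (pair == MISSING).sum(axis=1)
            if np.any(half == 1):
                raise ValueError(
                    f"half-missing genotype at {locus.locus_id}: MISSING has no alleles"
                )

    # -- basic accessors -------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def sample_indices(
        self, species: str | None = None, cohort: str | None = None
    ) -> np.ndarray:
        keep = [
            j
            for j, s in enumerate(self.samples)
            if (species is None or s.species == species)
            and (cohort is None or s.cohort == cohort)
        ]
        return np.asarray(keep, dtype=int)

    def is_missing(self) -> np.ndarray:
        """Boolean (loci, samples) mask of MISSING genotypes."""
        return self.gt[:, :, 0] == MISSING

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            loci=list(self.loci),
            samples=list(self.samples),
            gt=self.gt.copy(),
            prov=self.prov.copy(),
        )

    def subset_loci(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            loci=[self.loci[i] for i in index],
            samples=list(self.samples),
            gt=self.gt[index].copy(),
            prov=self.prov[index].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.samples == other.samples
            and np.array_equal(self.gt, other.gt)
            and np.array_equal(self.prov, other.prov)
        )


# ---------------------------------------------------------------------------
# metadata ingestion


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read a sample metadata TSV: ``sample<TAB>species<TAB>cohort<TAB>mother``.

    The mother column uses ``.`` or empty for adults. Every seedling's
    mother must resolve to an adult row in the same table.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample", "species", "cohort", "mother"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"metadata {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    metas = []
    for row in df.itertuples(index=False):
        mother = row.mother if row.mother not in ("", ".") else None
        metas.append(SampleMeta(row.sample, row.species, row.cohort, mother))
    validate_pedigree(metas)
    return metas


def validate_pedigree(metas: Iterable[SampleMeta]) -> None:
    adults = {m.sample_id for m in metas if m.cohort == "adult"}
    for m in metas:
        if m.mother_id is not None and m.mother_id not in adults:
            raise ValueError(
                f"mother {m.mother_id!r} of seedling {m.sample_id!r} "
                "does not resolve to an adult sample"
            )


def write_sample_metadata(metas: Sequence[SampleMeta], path: str | Path) -> None:
    rows = [
        (m.sample_id, m.species, m.cohort, m.mother_id or ".") for m in metas
    ]
    pd.DataFrame(rows, columns=["sample", "species", "cohort", "mother"]).to_csv(
        path, sep="\t", index=False
    )


def load_family_sizes() -> pd.DataFrame:
    """Bundled open-pollinated family design of the field study.

    One row per mother tree with its species and the number of genotyped
    seedlings collected from its canopy. Hybrid mother trees carry FS ids;
    the unrelated pure-species mothers carry E (holm oak) and A (cork oak)
    ids.
    """
    with resources.files("hybridrad.data").joinpath(
        "open_pollinated_families.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def cohort_totals(families: pd.DataFrame | None = None) -> dict[str, int]:
    """Total seedlings per mother-tree species from the family table."""
    if families is None:
        families = load_family_sizes()
    return families.groupby("species")["n_seedlings"].sum().astype(int).to_dict()


# ---------------------------------------------------------------------------
# VCF ingestion


def _locus_sort_key(locus: Locus) -> tuple:
    return (locus.chrom, locus.pos, locus.ref, locus.alts)


def read_merged_vcf(
    path: str | Path, meta: Sequence[SampleMeta]
) -> GenotypeMatrix:
    """Read a merged multi-sample VCF into a :class:`GenotypeMatrix`.

    Every VCF sample column must have a metadata row (extra metadata rows
    are ignored). ``./.`` maps to MISSING; phased separators are treated as
    unphased; multi-allelic records keep their ALT indices. Loci are
    ordered by (chrom, pos) regardless of input record order. Ploidy other
    than 2 is a hard error.

    Per-locus total depth is the sum of per-sample FORMAT/DP values when
    the FORMAT field is present, else the INFO/DP value; the source used
    is logged once per file.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    by_id = {m.sample_id: m for m in meta}
    samples: list[SampleMeta] = []
    for name in vcf.samples:
        if name not in by_id:
            raise ValueError(f"VCF sample {name!r} absent from sample metadata")
        samples.append(by_id[name])
    validate_pedigree(samples)

    loci: list[Locus] = []
    rows: list[np.ndarray] = []
    depth_sources: set[str] = set()
    n_samples = len(samples)
    for rec_no, v in enumerate(vcf, start=1):
        gts = np.asarray([g[:-1] for g in v.genotypes], dtype=np.int64)
        if gts.shape != (n_samples, 2):
            raise ValueError(
                f"record {rec_no} ({v.CHROM}:{v.POS}): non-diploid genotype "
                "field; this model is strictly diploid"
            )
        pair = gts.astype(np.int16)
        # any partially-missing call collapses to MISSING
        miss = (pair < 0).any(axis=1)
        pair[miss] = MISSING

        depth = _total_depth(v, n_samples, depth_sources)
        loci.append(
            Locus(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                total_depth=depth,
            )
        )
        rows.append(pair)

    order = sorted(range(len(loci)), key=lambda i: _locus_sort_key(loci[i]))
    loci = [loci[i] for i in order]
    gt = (
        np.stack([rows[i] for i in order], axis=0)
        if rows
        else np.empty((0, n_samples, 2), dtype=np.int16)
    )
    if depth_sources:
        logger.info("total depth for %s from %s", path, "+".join(sorted(depth_sources)))
    return GenotypeMatrix(loci=loci, samples=samples, gt=gt)


def _total_depth(variant, n_samples: int, sources: set[str]) -> int | None:
    fmt_dp = None
    try:
        fmt_dp = variant.format("DP")
    except KeyError:
        fmt_dp = None
    if fmt_dp is not None:
        dp = np.asarray(fmt_dp).reshape(n_samples, -1)[:, 0].astype(np.int64)
        sources.add("FORMAT/DP")
        return int(dp[dp >= 0].sum())
    info_dp = variant.INFO.get("DP")
    if info_dp is not None:
        sources.add("INFO/DP")
        return int(info_dp)
    return None


def filter_by_total_depth(m: GenotypeMatrix, dp_min: int = 6000) -> GenotypeMatrix:
    """Keep exactly the loci with total read depth >= ``dp_min``.

    The headline coverage filter discards low-coverage loci (total reads
    across all samples below the threshold). Depth must be available at
    every locus; the filter refuses to be silently skipped.
    """
    missing_dp = [l.locus_id for l in m.loci if l.total_depth is None]
    if missing_dp:
        raise ValueError(
            f"total depth unavailable at {len(missing_dp)} loci "
            f"(first: {missing_dp[0]}); cannot apply depth filter"
        )
    keep = [i for i, l in enumerate(m.loci) if l.total_depth >= dp_min]
    return m.subset_loci(keep)


# ---------------------------------------------------------------------------
# serialization (round-trippable VCF + provenance sidecar)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth across samples">
##INFO=<ID=RG,Number=1,Type=String,Description="Region class (exon/intron/intergenic/unassigned)">
##INFO=<ID=FRAG,Number=1,Type=String,Description="Gene or intergenic fragment id">
##ALT=<ID=NULL,Description="Imputed restriction-site dropout (null) allele">
"""


def provenance_sidecar_path(vcf_path: str | Path) -> Path:
    return Path(str(vcf_path) + ".prov.tsv")


def write_matrix(m: GenotypeMatrix, path: str | Path) -> Path:
    """Serialize a matrix to VCF plus a provenance sidecar TSV.

    NULL alleles are encoded as an extra symbolic ALT ``<NULL>``; sample
    metadata is embedded in ``##SAMPLE`` header lines so that
    :func:`read_matrix` restores loci, samples, genotypes and provenance
    exactly.
    """
    path = Path(path)
    lines = [_VCF_HEADER.rstrip("\n")]
    for chrom in dict.fromkeys(l.chrom for l in m.loci):
        lines.append(f"##contig=<ID={chrom}>")
    for s in m.samples:
        lines.append(
            f"##SAMPLE=<ID={s.sample_id},Species={s.species},"
            f"Cohort={s.cohort},Mother={s.mother_id or '.'}>"
        )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(m.sample_ids)
    )
    for i, locus in enumerate(m.loci):
        has_null = np.any(m.gt[i] == NULL)
        alts = list(locus.alts) + ([NULL_SYMBOL] if has_null else [])
        null_idx = len(locus.alts) + 1  # VCF index of <NULL> when present
        info = []
        if locus.total_depth is not None:
            info.append(f"DP={locus.total_depth}")
        info.append(f"RG={locus.region}")
        if locus.fragment_id is not None:
            info.append(f"FRAG={locus.fragment_id}")
        cells = []
        for j in range(m.n_samples):
            a, b = m.gt[i, j]
            if a == MISSING:
                cells.append("./.")
            else:
                va = null_idx if a == NULL else int(a)
                vb = null_idx if b == NULL else int(b)
                cells.append(f"{va}/{vb}")
        lines.append(
            "\t".join(
                [
                    locus.chrom,
                    str(locus.pos),
                    ".",
                    locus.ref,
                    ",".join(alts) if alts else ".",
                    ".",
                    ".",
                    ";".join(info) if info else ".",
                    "GT",
                ]
                + cells
            )
        )
    path.write_text("\n".join(lines) + "\n")

    prov_rows = []
    li, sj = np.nonzero(m.prov != OBSERVED)
    for i, j in zip(li.tolist(), sj.tolist()):
        prov_rows.append(
            (m.loci[i].locus_id, m.samples[j].sample_id, PROVENANCE_NAMES[int(m.prov[i, j])])
        )
    pd.DataFrame(prov_rows, columns=["locus", "sample", "provenance"]).to_csv(
        provenance_sidecar_path(path), sep="\t", index=False
    )
    return path


def _parse_sample_header(line: str) -> SampleMeta:
    body = line[len("##SAMPLE=<") :].rstrip(">")
    kv = dict(item.split("=", 1) for item in body.split(","))
    mother = kv.get("Mother", ".")
    return SampleMeta(
        sample_id=kv["ID"],
        species=kv["Species"],
        cohort=kv["Cohort"],
        mother_id=None if mother == "." else mother,
    )


def read_matrix(path: str | Path) -> GenotypeMatrix:
    """Inverse of :func:`write_matrix` (including provenance flags)."""
    path = Path(path)
    metas: list[SampleMeta] = []
    loci: list[Locus] = []
    rows: list[list[tuple[int, int]]] = []
    sample_names: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##SAMPLE=<"):
                metas.append(_parse_sample_header(line))
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                sample_names = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            chrom, pos, _, ref, alt = fields[:5]
            info = fields[7]
            alts = tuple(alt.split(",")) if alt != "." else ()
            has_null = alts and alts[-1] == NULL_SYMBOL
            declared = alts[:-1] if has_null else alts
            null_idx = len(declared) + 1
            kv = dict(
                item.split("=", 1) for item in info.split(";") if "=" in item
            )
            loci.append(
                Locus(
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alts=declared,
                    total_depth=int(kv["DP"]) if "DP" in kv else None,
                    region=kv.get("RG", "unassigned"),
                    fragment_id=kv.get("FRAG"),
                )
            )
            row = []
            for cell in fields[9:]:
                gt_str = cell.split(":")[0].replace("|", "/")
                if "." in gt_str:
                    row.append((MISSING, MISSING))
                else:
                    a, b = (int(x) for x in gt_str.split("/"))
                    a = NULL if has_null and a == null_idx else a
                    b = NULL if has_null and b == null_idx else b
                    row.append((a, b))
            rows.append(row)

    by_id = {s.sample_id: s for s in metas}
    samples = [by_id[name] for name in sample_names]
    gt = (
        np.asarray(rows, dtype=np.int16)
        if rows
        else np.empty((0, len(samples), 2), dtype=np.int16)
    )
    m = GenotypeMatrix(loci=loci, samples=samples, gt=gt)

    prov_path = provenance_sidecar_path(path)
    if prov_path.exists():
        prov_df = pd.read_csv(prov_path, sep="\t", dtype=str)
        lidx = {lid: i for i, lid in enumerate(m.locus_ids)}
        sidx = {sid: j for j, sid in enumerate(m.sample_ids)}
        for row in prov_df.itertuples(index=False):
            m.prov[lidx[row.locus], sidx[row.sample]] = PROVENANCE_CODES[row.provenance]
    return m
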