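"""Two-step imputation/filtering procedure and mother-based progeny correction.

ddRADseq loci can drop out of one species entirely when a restriction site
is mutated or methylated there: heterozygous carriers of such a "null"
allele look homozygous and homozygous carriers look missing. The engine
detects this species-conditional missingness signature among the adult
parental populations and builds four genotype-matrix scenarios:

* **Scenario I** — at each imputable locus (missingness md < 0.05 in one
  parental species and md > 0.90 in the other), adults of the high-md
  species get a null allele: MISSING becomes {NULL, NULL} and homozygotes
  {X, X} become {X, NULL}.
* **Scenario II** — Scenario I thinned to one imputed locus per gene or
  intergenic fragment (intergenic fragments built with a 10 kb proximity
  window).
* **Scenario III** — Scenario I with every imputed allele reverted and
  treated as missing data again.
* **Scenario IV** — the unimputed matrix with every locus of md > 0.90 in
  either parental species discarded.

Seedling genotypes are then corrected against their mother tree: calls
that cannot share an allele with the mother under any dropout-aware
reinterpretation are blanked as Mendelian-incompatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hybridrad.core_data import (
    CORRECTED_TO_MISSING,
    IMPUTED_NULL,
    MENDEL_RECODED,
    MISSING,
    NULL,
    OBSERVED,
    GenotypeMatrix,
    Locus,
    SampleMeta,
)

MD_LOW_DEFAULT = 0.05
MD_HIGH_DEFAULT = 0.90
INTERGENIC_WINDOW_DEFAULT = 10_000

PARENTAL_SPECIES = ("ilex", "suber")


@dataclass(frozen=True)
class MissingnessProfile:
    """Per-locus fraction of MISSING genotypes among adults of each parental species."""

    locus_ids: tuple[str, ...]
    md_ilex: np.ndarray
    md_suber: np.ndarray
    n_adults_ilex: int
    n_adults_suber: int

    def md(self, species: str) -> np.ndarray:
        if species == "ilex":
            return self.md_ilex
        if species == "suber":
            return self.md_suber
        raise KeyError(species)


@dataclass(frozen=True)
class ImputationRule:
    """Thresholds of the null-allele imputation criterion (strict inequalities)."""

    md_low: float = MD_LOW_DEFAULT
    md_high: float = MD_HIGH_DEFAULT


@dataclass(frozen=True)
class FragmentIndex:
    """Per-locus fragment assignment (gene id or intergenic cluster)."""

    fragment_ids: Mapping[str, str]  # locus_id -> fragment id ("unassigned" allowed)
    regions: Mapping[str, str]  # locus_id -> exon | intron | intergenic | unassigned


@dataclass
class ScenarioResult:
    """A genotype matrix specialized to one imputation scenario."""

    scenario: str  # I | II | III | IV
    matrix: GenotypeMatrix
    imputed_loci: dict[str, str] = field(default_factory=dict)  # locus_id -> direction

    @property
    def n_loci(self) -> int:
        return self.matrix.n_loci

    @property
    def n_imputed(self) -> int:
        return len(set(self.imputed_loci) & set(self.matrix.locus_ids))


# ---------------------------------------------------------------------------
# missingness and imputable loci


def compute_missingness(m: GenotypeMatrix) -> MissingnessProfile:
    """Fraction of missing genotypes per locus among adults of each parental species.

    Hybrids and seedlings never enter the computation; the denominator is
    the number of adult individuals of the species.
    """
    miss = m.is_missing()
    mds = {}
    ns = {}
    for sp in PARENTAL_SPECIES:
        idx = m.sample_indices(species=sp, cohort="adult")
        if idx.size == 0:
            raise ValueError(f"no adult {sp} individuals in matrix")
        mds[sp] = miss[:, idx].mean(axis=1)
        ns[sp] = int(idx.size)
    return MissingnessProfile(
        locus_ids=tuple(m.locus_ids),
        md_ilex=mds["ilex"],
        md_suber=mds["suber"],
        n_adults_ilex=ns["ilex"],
        n_adults_suber=ns["suber"],
    )


def identify_imputable_loci(
    p: MissingnessProfile, rule: ImputationRule = ImputationRule()
) -> dict[str, str]:
    """Loci qualifying for null-allele imputation, with their direction.

    A locus qualifies iff missingness is strictly below ``md_low`` in one
    parental species and strictly above ``md_high`` in the other; the
    direction names the high-md species (``null_in_ilex`` /
    ``null_in_suber``). Boundary values do not qualify.
    """
    out: dict[str, str] = {}
    for lid, mi, ms in zip(p.locus_ids, p.md_ilex, p.md_suber):
        if ms < rule.md_low and mi > rule.md_high:
            out[lid] = "null_in_ilex"
        elif mi < rule.md_low and ms > rule.md_high:
            out[lid] = "null_in_suber"
    return out


# ---------------------------------------------------------------------------
# scenarios


def build_scenario_I(m: GenotypeMatrix, imp: Mapping[str, str]) -> ScenarioResult:
    """Impute null alleles into the high-md species at qualifying loci.

    For adult individuals of the high-md species: MISSING becomes
    {NULL, NULL}; homozygotes {X, X} become {X, NULL}; heterozygotes are
    left untouched. All edits are flagged ``imputed_null``; the other
    species' genotypes are never modified.
    """
    out = m.copy()
    adult_idx = {
        sp: out.sample_indices(species=sp, cohort="adult") for sp in PARENTAL_SPECIES
    }
    lidx = {lid: i for i, lid in enumerate(out.locus_ids)}
    for lid, direction in imp.items():
        i = lidx[lid]
        sp = "ilex" if direction == "null_in_ilex" else "suber"
        for j in adult_idx[sp]:
            a, b = out.gt[i, j]
            if a == MISSING:
                out.gt[i, j] = (NULL, NULL)
                out.prov[i, j] = IMPUTED_NULL
            elif a == b:
                out.gt[i, j] = (NULL, a)
                out.prov[i, j] = IMPUTED_NULL
    out.gt = np.sort(out.gt, axis=2)
    return ScenarioResult(scenario="I", matrix=out, imputed_loci=dict(imp))


def build_scenario_III(s1: ScenarioResult) -> ScenarioResult:
    """Revert every imputed allele, treating it as missing data again.

    {NULL, NULL} goes back to MISSING and {X, NULL} back to {X, X}; the
    locus set is identical to Scenario I. Composition with
    :func:`build_scenario_I` is the identity on genotypes.
    """
    out = s1.matrix.copy()
    li, sj = np.nonzero(out.prov == IMPUTED_NULL)
    for i, j in zip(li.tolist(), sj.tolist()):
        a, b = out.gt[i, j]
        if a == NULL and b == NULL:
            out.gt[i, j] = (MISSING, MISSING)
        else:
            x = b if a == NULL else a
            out.gt[i, j] = (x, x)
        out.prov[i, j] = OBSERVED
    return ScenarioResult(scenario="III", matrix=out, imputed_loci={})


def build_scenario_IV(
    m: GenotypeMatrix,
    p: MissingnessProfile | None = None,
    md_high: float = MD_HIGH_DEFAULT,
) -> ScenarioResult:
    """Discard loci with missingness strictly above ``md_high`` in either
    parental adult population; no imputation anywhere."""
    if p is None:
        p = compute_missingness(m)
    keep = [
        i
        for i in range(m.n_loci)
        if not (p.md_ilex[i] > md_high or p.md_suber[i] > md_high)
    ]
    return ScenarioResult(scenario="IV", matrix=m.subset_loci(keep), imputed_loci={})


# ---------------------------------------------------------------------------
# fragments and Scenario II


def assign_fragments(
    loci: Sequence[Locus],
    annotation: str | Path,
    window: int = INTERGENIC_WINDOW_DEFAULT,
) -> FragmentIndex:
    """Assign each locus to a gene fragment or a 10 kb-window intergenic fragment.

    A locus inside an annotated gene span takes that gene's id as fragment;
    its region is ``exon`` if it falls in an exon sub-feature, else
    ``intron``. Remaining loci are clustered per chromosome by
    single-linkage on position with gap <= ``window`` into intergenic
    fragments. Loci on chromosomes absent from the annotation stay
    ``unassigned`` (with a warning, not an error).
    """
    import warnings

    import gffutils

    db = gffutils.create_db(
        str(annotation),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    known_chroms = {f.seqid for f in db.all_features()}

    fragment_ids: dict[str, str] = {}
    regions: dict[str, str] = {}
    intergenic: dict[str, list[tuple[int, str]]] = {}

    for locus in loci:
        lid = locus.locus_id
        if locus.chrom not in known_chroms:
            warnings.warn(
                f"chromosome {locus.chrom!r} absent from annotation; "
                f"locus {lid} left unassigned"
            )
            fragment_ids[lid] = "unassigned"
            regions[lid] = "unassigned"
            continue
        genes = [
            g
            for g in db.region((locus.chrom, locus.pos - 1, locus.pos))
            if g.featuretype == "gene"
        ]
        if genes:
            gene = min(genes, key=lambda g: (g.start, g.id))
            fragment_ids[lid] = f"gene:{gene.id}"
            in_exon = any(
                e.start <= locus.pos <= e.end
                for e in db.children(gene, featuretype="exon")
            )
            regions[lid] = "exon" if in_exon else "intron"
        else:
            intergenic.setdefault(locus.chrom, []).append((locus.pos, lid))

    for chrom, entries in intergenic.items():
        entries.sort()
        cluster = 0
        prev_pos = None
        for pos, lid in entries:
            if prev_pos is not None and pos - prev_pos > window:
                cluster += 1
            fragment_ids[lid] = f"intergenic:{chrom}:{cluster}"
            regions[lid] = "intergenic"
            prev_pos = pos
    return FragmentIndex(fragment_ids=fragment_ids, regions=regions)


def annotate_matrix(m: GenotypeMatrix, f: FragmentIndex) -> GenotypeMatrix:
    """Return a copy of ``m`` with region/fragment_id stamped onto each locus."""
    from dataclasses import replace

    out = m.copy()
    out.loci = [
        replace(
            l,
            region=f.regions.get(l.locus_id, "unassigned"),
            fragment_id=f.fragment_ids.get(l.locus_id, "unassigned"),
        )
        for l in out.loci
    ]
    return out


def build_scenario_II(
    s1: ScenarioResult,
    f: FragmentIndex,
    tie_break: str = "position",
) -> ScenarioResult:
    """Thin Scenario I to at most one imputed locus per fragment.

    Non-imputed loci are never dropped. Within a fragment holding several
    imputed loci the one with the smallest (chrom, pos) is kept
    (deterministic, annotation-independent tie-break).
    """
    if tie_break != "position":
        raise ValueError(f"unknown tie_break {tie_break!r}")
    m = s1.matrix
    keep = np.ones(m.n_loci, dtype=bool)
    by_fragment: dict[str, list[int]] = {}
    for i, locus in enumerate(m.loci):
        lid = locus.locus_id
        if lid in s1.imputed_loci:
            frag = f.fragment_ids.get(lid, "unassigned")
            by_fragment.setdefault(frag, []).append(i)
    for frag, idxs in by_fragment.items():
        idxs.sort(key=lambda i: (m.loci[i].chrom, m.loci[i].pos))
        for i in idxs[1:]:
            keep[i] = False
    out = m.subset_loci(np.nonzero(keep)[0])
    kept_ids = set(out.locus_ids)
    imputed = {
        lid: d for lid, d in s1.imputed_loci.items() if lid in kept_ids
    }
    return ScenarioResult(scenario="II", matrix=out, imputed_loci=imputed)


# ---------------------------------------------------------------------------
# mother-offspring correction


def _resolutions(
    genotype: tuple[int, int], imputed: bool
) -> list[tuple[int, int]]:
    """Dropout-aware readings of an observed offspring genotype.

    The direct reading always comes first (minimal change). At imputed
    loci an apparent homozygote {X, X} may really be {X, NULL}, because a
    null allele hides behind the scored one; apparent heterozygotes
    amplified both alleles and admit no reinterpretation.
    """
    a, b = genotype
    out = [(a, b)]
    if imputed and a == b and a != NULL:
        out.append(tuple(sorted((a, NULL))))
    return out


def mendel_compatible(
    offspring: tuple[int, int], mother: tuple[int, int]
) -> bool:
    """True iff the offspring genotype can contain a maternal gamete."""
    return bool(set(offspring) & set(mother))


def correct_progeny(
    s: ScenarioResult, meta: Sequence[SampleMeta] | None = None
) -> ScenarioResult:
    """Blank or recode seedling genotypes incompatible with their mother tree.

    Per seedling per locus: if some dropout-aware resolution of the
    observed genotype shares at least one allele with the mother's
    genotype, the minimal-change compatible resolution is kept (flagged
    ``mendel_recoded`` when it differs from the observation); if none is
    compatible, the genotype is set to MISSING (``corrected_to_missing``).
    A MISSING mother leaves the offspring untouched. Adults are never
    altered, and the operation is idempotent.
    """
    m = s.matrix.copy()
    samples = m.samples if meta is None else list(meta)
    sidx = {smp.sample_id: j for j, smp in enumerate(m.samples)}
    imputed = set(s.imputed_loci)
    lids = m.locus_ids
    for smp in samples:
        if smp.cohort != "seedling":
            continue
        if smp.sample_id not in sidx:
            continue
        j = sidx[smp.sample_id]
        if smp.mother_id not in sidx:
            raise ValueError(
                f"mother {smp.mother_id!r} of seedling {smp.sample_id!r} "
                "absent from matrix"
            )
        jm = sidx[smp.mother_id]
        for i in range(m.n_loci):
            a, b = (int(x) for x in m.gt[i, j])
            if a == MISSING:
                continue
            ma, mb = (int(x) for x in m.gt[i, jm])
            if ma == MISSING:
                continue
            mother = (ma, mb)
            chosen = None
            for res in _resolutions((a, b), lids[i] in imputed):
                if mendel_compatible(res, mother):
                    chosen = res
                    break
            if chosen is None:
                m.gt[i, j] = (MISSING, MISSING)
                m.prov[i, j] = CORRECTED_TO_MISSING
            elif chosen != (a, b):
                m.gt[i, j] = chosen
                m.prov[i, j] = MENDEL_RECODED
    m.gt = np.sort(m.gt, axis=2)
    return ScenarioResult(
        scenario=s.scenario, matrix=m, imputed_loci=dict(s.imputed_loci)
    )


# ---------------------------------------------------------------------------
# convenience driver + reporting


def build_all_scenarios(
    m: GenotypeMatrix,
    annotation: str | Path | None = None,
    rule: ImputationRule = ImputationRule(),
    window: int = INTERGENIC_WINDOW_DEFAULT,
    correct: bool = True,
) -> dict[str, ScenarioResult]:
    """Run the full two-step procedure and return Scenarios I-IV.

    ``annotation`` (GFF3) is required for Scenario II; without it only
    I, III and IV are produced. When ``correct`` is true, seedling
    genotypes are corrected against their mothers in every scenario.
    """
    profile = compute_missingness(m)
    imp = identify_imputable_loci(profile, rule)
    s1 = build_scenario_I(m, imp)
    results = {"I": s1, "III": build_scenario_III(s1), "IV": build_scenario_IV(m, profile)}
    if annotation is not None:
        frags = assign_fragments(m.loci, annotation, window=window)
        s1.matrix = annotate_matrix(s1.matrix, frags)
        results["II"] = build_scenario_II(s1, frags)
        for key in ("III", "IV"):
            results[key].matrix = annotate_matrix(results[key].matrix, frags)
    if correct:
        results = {k: correct_progeny(v) for k, v in results.items()}
    return results


def imputed_fraction(n_imputed: int, n_total: int) -> float:
    """Share of imputed loci in a scenario, as a fraction of its locus count."""
    if n_total <= 0:
        raise ValueError("scenario has no loci")
    return n_imputed / n_total


def thinned_imputed_count(
    n_imputed_before: int, n_loci_before: int, n_loci_after: int
) -> int:
    """Imputed loci surviving fragment thinning.

    Thinning drops imputed loci only, so the count after equals the count
    before minus the loci removed between the two scenarios.
    """
    dropped = n_loci_before - n_loci_after
    if dropped < 0 or dropped > n_imputed_before:
        raise ValueError("thinning cannot add loci or drop more than the imputed set")
    return n_imputed_before - dropped


def scenario_report(s: ScenarioResult) -> pd.DataFrame:
    """Locus counts by variant type and region class for one scenario."""
    rows = []
    imputed = set(s.imputed_loci)
    for locus in s.matrix.loci:
        rows.append(
            {
                "scenario": s.scenario,
                "variant_type": locus.variant_type,
                "region": locus.region,
                "imputed": locus.locus_id in imputed,
            }
        )
    df = pd.DataFrame(rows, columns=["scenario", "variant_type", "region", "imputed"])
    return (
        df.groupby(["scenario", "variant_type", "region", "imputed"])
        .size()
        .rename("n_loci")
        .reset_index()
    )
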