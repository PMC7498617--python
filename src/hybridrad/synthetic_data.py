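"""Forward pedigree simulator for two hybridizing parental species.

Generates everything the pipeline consumes, synthetically: two parental
adult populations with species-specific restriction-site dropout (null)
alleles and background missingness, adult hybrids, pedigreed virtual
individuals across twenty ancestry categories, open-pollinated progeny
arrays with known pollen-donor sources, and on-disk fixtures (VCF,
metadata, truth table, toy GFF3 annotation, anchor table).

Loci are unlinked and diploid; three allele states per locus (REF, one
ALT, and optionally NULL). Locus classes:

* *diagnostic* — fixed REF in ilex, fixed ALT in suber;
* *dropout* — a NULL allele at high frequency (default fixed) in one
  species, absent in the other; the observation model renders its
  carriers as missing data or apparent homozygotes, reproducing the
  species-conditional missingness signature the scenario engine detects;
* *shared* — one biallelic frequency drawn from a background
  distribution and common to both species.

Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hybridrad.core_data import MISSING, NULL

DEFAULT_HYBRID_FAMILY_SIZES = (12, 19, 47, 26, 16, 57, 30, 5, 68)  # 280 seedlings


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulator.

    Adult sample sizes default to the field design (99 holm oaks, 98 cork
    oaks, 22 adult hybrids). The locus panel defaults to a desk-scale
    1,000 loci whose composition mirrors the real marker panel: ~21.9%
    dropout loci (most with the null allele in ilex) and a sizeable
    diagnostic fraction; ~2.6% of shared loci are indels.
    """

    n_loci: int = 1000
    n_diagnostic: int | None = None  # default: 20% of n_loci
    n_dropout_ilex: int | None = None  # default: 18% of n_loci
    n_dropout_suber: int | None = None  # default: 3.9% of n_loci
    n_adults_ilex: int = 99
    n_adults_suber: int = 98
    n_adult_hybrids: int = 22
    background_freq_low: float = 0.05
    background_freq_high: float = 0.95
    dropout_freq: float = 1.0  # NULL frequency in the affected species
    md_background: float = 0.02  # random per-genotype missingness
    indel_fraction: float = 0.026
    n_low_depth: int = 20  # loci planted below the coverage filter
    n_chroms: int = 12
    depth_mean: int = 70  # reads per sample per retained locus
    depth_mean_low: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diagnostic is None:
            object.__setattr__(self, "n_diagnostic", round(0.20 * self.n_loci))
        if self.n_dropout_ilex is None:
            object.__setattr__(self, "n_dropout_ilex", round(0.18 * self.n_loci))
        if self.n_dropout_suber is None:
            object.__setattr__(self, "n_dropout_suber", round(0.039 * self.n_loci))
        if self.n_diagnostic + self.n_dropout_ilex + self.n_dropout_suber > self.n_loci:
            raise ValueError("special loci exceed n_loci")
        for r in (self.md_background, self.dropout_freq, self.indel_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def n_shared(self) -> int:
        return self.n_loci - self.n_diagnostic - self.n_dropout_ilex - self.n_dropout_suber


@dataclass
class Individuals:
    """A batch of diploid virtual individuals with per-allele-copy ancestry."""

    ids: list[str]
    gt: np.ndarray  # (n, L, 2) allele codes: NULL, 0 (REF), 1 (ALT)
    anc: np.ndarray  # (n, L, 2) suber-origin indicator per allele copy

    @property
    def n(self) -> int:
        return len(self.ids)

    def realized_h(self) -> np.ndarray:
        """Fraction of suber-origin allele copies actually inherited."""
        return self.anc.reshape(self.n, -1).mean(axis=1)

    def subset(self, idx: Sequence[int]) -> "Individuals":
        idx = list(idx)
        return Individuals(
            ids=[self.ids[i] for i in idx], gt=self.gt[idx], anc=self.anc[idx]
        )


def concat_individuals(parts: Sequence[Individuals]) -> Individuals:
    return Individuals(
        ids=[i for p in parts for i in p.ids],
        gt=np.concatenate([p.gt for p in parts], axis=0),
        anc=np.concatenate([p.anc for p in parts], axis=0),
    )


@dataclass
class ParentalPools:
    """Per-species allele distributions and the adult individuals drawn from them.

    ``probs[species]`` has shape (L, 3): the per-locus probabilities of
    drawing NULL, REF and ALT allele copies in that species.
    """

    cfg: SimConfig
    probs: dict[str, np.ndarray]
    adults: dict[str, Individuals]
    locus_class: np.ndarray  # 'diagnostic' | 'dropout_ilex' | 'dropout_suber' | 'shared'

    def dropout_locus_index(self) -> np.ndarray:
        return np.flatnonzero(
            (self.locus_class == "dropout_ilex") | (self.locus_class == "dropout_suber")
        )


_ALLELE_CODES = np.array([NULL, 0, 1], dtype=np.int16)


def _draw_copies(probs: np.ndarray, shape: tuple, rng: np.random.Generator) -> np.ndarray:
    """Draw allele copies (codes) for each of ``shape[-1]`` copies at L loci."""
    # probs: (L, 3) over (NULL, REF, ALT); shape's last axis must be L
    u = rng.random(shape)
    out = np.empty(shape, dtype=np.int16)
    c0 = probs[:, 0]  # broadcasts over the leading axes; last axis is L
    c1 = probs[:, 0] + probs[:, 1]
    out[...] = 1
    out[u < c1] = 0
    out[u < c0] = NULL
    return out


def _hwe_individuals(
    probs: np.ndarray, n: int, species_anc: int, prefix: str, rng: np.random.Generator
) -> Individuals:
    L = probs.shape[0]
    gt = np.stack(
        [_draw_copies(probs, (n, L), rng), _draw_copies(probs, (n, L), rng)], axis=2
    )
    anc = np.full((n, L, 2), species_anc, dtype=np.int8)
    ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    return Individuals(ids=ids, gt=np.sort(gt, axis=2), anc=anc)


def simulate_parental_pools(cfg: SimConfig, rng: np.random.Generator | None = None) -> ParentalPools:
    """Build per-species allele distributions and draw the adult populations.

    Diagnostic loci are fixed for alternative alleles across species;
    dropout loci carry NULL at ``dropout_freq`` in the designated species
    and never in the other; shared loci get a single background ALT
    frequency used by both species. Adults are sampled under
    Hardy-Weinberg within species.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    locus_class = np.array(["shared"] * L, dtype=object)
    locus_class[: cfg.n_diagnostic] = "diagnostic"
    a = cfg.n_diagnostic
    locus_class[a : a + cfg.n_dropout_ilex] = "dropout_ilex"
    b = a + cfg.n_dropout_ilex
    locus_class[b : b + cfg.n_dropout_suber] = "dropout_suber"

    p_bg = rng.uniform(cfg.background_freq_low, cfg.background_freq_high, size=L)
    probs = {sp: np.zeros((L, 3)) for sp in ("ilex", "suber")}
    for i in range(L):
        cls = locus_class[i]
        if cls == "diagnostic":
            probs["ilex"][i] = (0.0, 1.0, 0.0)
            probs["suber"][i] = (0.0, 0.0, 1.0)
        elif cls == "dropout_ilex":
            probs["ilex"][i] = (cfg.dropout_freq, 1.0 - cfg.dropout_freq, 0.0)
            probs["suber"][i] = (0.0, 1.0, 0.0)
        elif cls == "dropout_suber":
            probs["suber"][i] = (cfg.dropout_freq, 1.0 - cfg.dropout_freq, 0.0)
            probs["ilex"][i] = (0.0, 1.0, 0.0)
        else:
            p = p_bg[i]
            probs["ilex"][i] = (0.0, 1.0 - p, p)
            probs["suber"][i] = (0.0, 1.0 - p, p)

    adults = {
        "ilex": _hwe_individuals(probs["ilex"], cfg.n_adults_ilex, 0, "IL", rng),
        "suber": _hwe_individuals(probs["suber"], cfg.n_adults_suber, 1, "SU", rng),
    }
    return ParentalPools(cfg=cfg, probs=probs, adults=adults, locus_class=locus_class)


def simulate_cross(
    mother: Individuals,
    father: Individuals,
    n: int,
    rng: np.random.Generator,
    prefix: str = "X",
    mother_idx: np.ndarray | None = None,
    father_idx: np.ndarray | None = None,
) -> Individuals:
    """Mendelian sampling: each offspring gets one uniformly chosen allele
    per parent per locus; NULL is inherited like any other allele.

    Parents for each offspring are drawn uniformly from the two batches
    unless explicit indices are given. Loci are independent (no linkage).
    """
    L = mother.gt.shape[1]
    if n == 0:
        return Individuals(
            ids=[],
            gt=np.empty((0, L, 2), dtype=np.int16),
            anc=np.empty((0, L, 2), dtype=np.int8),
        )
    mi = rng.integers(mother.n, size=n) if mother_idx is None else np.asarray(mother_idx)
    fi = rng.integers(father.n, size=n) if father_idx is None else np.asarray(father_idx)
    pick_m = rng.integers(2, size=(n, L))
    pick_f = rng.integers(2, size=(n, L))
    rows = np.arange(L)
    gt = np.empty((n, L, 2), dtype=np.int16)
    anc = np.empty((n, L, 2), dtype=np.int8)
    for o in range(n):
        gt[o, :, 0] = mother.gt[mi[o], rows, pick_m[o]]
        anc[o, :, 0] = mother.anc[mi[o], rows, pick_m[o]]
        gt[o, :, 1] = father.gt[fi[o], rows, pick_f[o]]
        anc[o, :, 1] = father.anc[fi[o], rows, pick_f[o]]
    order = np.argsort(gt, axis=2, kind="stable")
    gt = np.take_along_axis(gt, order, axis=2)
    anc = np.take_along_axis(anc, order, axis=2)
    ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    return Individuals(ids=ids, gt=gt, anc=anc)


# ---------------------------------------------------------------------------
# pedigree categories


def default_category_recipes() -> list[tuple[str, tuple[str, str] | None]]:
    """The 20 default pedigree categories: two pure species plus 18
    intermediates (F1, F2, four backcross generations toward each
    species, and F1 x BCk crosses toward each species)."""
    recipes: list[tuple[str, tuple[str, str] | None]] = [
        ("pure_ilex", None),
        ("pure_suber", None),
        ("F1", ("pure_ilex", "pure_suber")),
        ("F2", ("F1", "F1")),
    ]
    for sp in ("suber", "ilex"):
        prev = "F1"
        for k in range(1, 5):
            name = f"BC{k}_{sp}"
            recipes.append((name, (prev, f"pure_{sp}")))
            prev = name
    for sp in ("suber", "ilex"):
        for k in range(1, 5):
            recipes.append((f"F1xBC{k}_{sp}", ("F1", f"BC{k}_{sp}")))
    return recipes


def expected_h_of_categories(
    recipes: Sequence[tuple[str, tuple[str, str] | None]]
) -> dict[str, float]:
    """Expected suber ancestry per category by the cross recursion
    h(X x Y) = (h(X) + h(Y)) / 2, anchored at the pure species."""
    h: dict[str, float] = {}
    for name, recipe in recipes:
        if recipe is None:
            h[name] = {"pure_ilex": 0.0, "pure_suber": 1.0}[name]
        else:
            pa, pb = recipe
            if pa not in h or pb not in h:
                raise ValueError(f"category {name!r} references an undefined parent")
            h[name] = (h[pa] + h[pb]) / 2.0
    return h


@dataclass
class CategorySet:
    """Virtual individuals of every pedigree category plus their truth table."""

    individuals: dict[str, Individuals]
    expected_h: dict[str, float]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for name, ind in self.individuals.items():
            for i, (iid, rh) in enumerate(zip(ind.ids, ind.realized_h())):
                rows.append(
                    {
                        "individual": iid,
                        "category": name,
                        "expected_h": self.expected_h[name],
                        "realized_h": float(rh),
                    }
                )
        return pd.DataFrame(rows, columns=["individual", "category", "expected_h", "realized_h"])

    def all_individuals(self) -> Individuals:
        return concat_individuals(list(self.individuals.values()))


def build_categories(
    pools: ParentalPools,
    n_per_category: int = 20,
    recipes: Sequence[tuple[str, tuple[str, str] | None]] | None = None,
    rng: np.random.Generator | None = None,
) -> CategorySet:
    """Generate ``n_per_category`` virtual individuals for each pedigree category.

    Pure categories are fresh Hardy-Weinberg draws from the species
    pools; crosses pick random parents from the already-built parent
    categories. Ancestry of every allele copy is tracked so each
    individual carries a realized (not just expected) suber fraction.
    """
    rng = rng or np.random.default_rng(pools.cfg.seed + 1)
    recipes = list(recipes) if recipes is not None else default_category_recipes()
    expected = expected_h_of_categories(recipes)
    built: dict[str, Individuals] = {}
    for name, recipe in recipes:
        if recipe is None:
            sp = "ilex" if name == "pure_ilex" else "suber"
            built[name] = _hwe_individuals(
                pools.probs[sp], n_per_category, 1 if sp == "suber" else 0,
                f"V_{name}_", rng,
            )
        else:
            pa, pb = recipe
            built[name] = simulate_cross(
                built[pa], built[pb], n_per_category, rng, prefix=f"V_{name}_"
            )
    return CategorySet(individuals=built, expected_h=expected)


# ---------------------------------------------------------------------------
# observation model


def apply_observation_model(
    gt: np.ndarray, md_background: float, rng: np.random.Generator
) -> np.ndarray:
    """Render true genotypes as the sequencer would score them.

    A {NULL, NULL} homozygote yields no scorable fragments and appears
    MISSING; a {X, NULL} heterozygote amplifies only the X copy and
    appears as the apparent homozygote {X, X}. Independently of dropout,
    each genotype is blanked to MISSING with probability
    ``md_background``. Truth is left untouched (a copy is returned).
    """
    obs = gt.copy()
    null_null = (gt == NULL).all(axis=2)
    obs[null_null] = MISSING
    one_null = (gt == NULL).sum(axis=2) == 1
    visible = gt.max(axis=2)
    obs[one_null, 0] = visible[one_null]
    obs[one_null, 1] = visible[one_null]
    if md_background > 0:
        drop = rng.random(gt.shape[:2]) < md_background
        obs[drop] = MISSING
    return np.sort(obs, axis=2)


# ---------------------------------------------------------------------------
# open pollination and reference panels


def simulate_open_pollination(
    mothers: Individuals,
    pools: ParentalPools,
    hybrid_pool: Individuals,
    family_sizes: Sequence[int],
    pollen_cloud: Mapping[str, float],
    rng: np.random.Generator,
    mother_ids: Sequence[str] | None = None,
    id_prefix: str = "SD",
) -> tuple[Individuals, pd.DataFrame]:
    """Open-pollinated families: each offspring's father is drawn from the
    pollen cloud (a mixture over the suber, ilex and hybrid pools).

    ``family_sizes[i]`` offspring are generated for mother ``i``. Returns
    the offspring batch and a truth frame recording each offspring's
    mother and father source. Cloud weights must sum to 1.
    """
    weights = {k: float(pollen_cloud.get(k, 0.0)) for k in ("suber", "ilex", "hybrid")}
    total_w = sum(weights.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError(f"pollen cloud weights sum to {total_w}, expected 1")
    if len(family_sizes) > mothers.n:
        raise ValueError("more families than mothers")
    mother_ids = list(mother_ids) if mother_ids is not None else mothers.ids

    father_pools = {
        "suber": pools.adults["suber"],
        "ilex": pools.adults["ilex"],
        "hybrid": hybrid_pool,
    }
    sources = ("suber", "ilex", "hybrid")
    probs = np.array([weights[s] for s in sources])

    parts: list[Individuals] = []
    rows = []
    counter = 1
    for fam_i, size in enumerate(family_sizes):
        for _ in range(int(size)):
            src = sources[rng.choice(3, p=probs)]
            fp = father_pools[src]
            child = simulate_cross(
                mothers.subset([fam_i]),
                fp,
                1,
                rng,
                prefix=f"{id_prefix}{counter:04d}_",
                mother_idx=np.array([0]),
            )
            child.ids = [f"{id_prefix}{counter:04d}"]
            parts.append(child)
            rows.append(
                {
                    "individual": child.ids[0],
                    "mother": mother_ids[fam_i],
                    "father_source": src,
                    "mother_realized_h": float(mothers.realized_h()[fam_i]),
                }
            )
            counter += 1
    offspring = concat_individuals(parts) if parts else Individuals(
        ids=[], gt=np.empty((0, mothers.gt.shape[1], 2), dtype=np.int16),
        anc=np.empty((0, mothers.gt.shape[1], 2), dtype=np.int8),
    )
    truth = pd.DataFrame(rows, columns=["individual", "mother", "father_source", "mother_realized_h"])
    return offspring, truth


def build_reference_panel(
    n_hybrids: int,
    prevalence: float,
    pools: ParentalPools,
    rng: np.random.Generator | None = None,
) -> tuple[Individuals, pd.DataFrame]:
    """Panel of F1 hybrids embedded among parental reference individuals.

    Total panel size is round(n_hybrids / prevalence); the parental
    remainder splits evenly between species with any odd individual going
    to ilex. ``prevalence`` of 1 yields a hybrids-only panel.
    """
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must lie in (0, 1]")
    rng = rng or np.random.default_rng(pools.cfg.seed + 2)
    total = round(n_hybrids / prevalence)
    n_parental = total - n_hybrids
    n_ilex = (n_parental + 1) // 2
    n_suber = n_parental - n_ilex
    hybrids = simulate_cross(
        pools.adults["ilex"], pools.adults["suber"], n_hybrids, rng, prefix="PH"
    )
    ilex = _hwe_individuals(pools.probs["ilex"], n_ilex, 0, "PI", rng)
    suber = _hwe_individuals(pools.probs["suber"], n_suber, 1, "PS", rng)
    panel = concat_individuals([hybrids, ilex, suber])
    roles = pd.DataFrame(
        {
            "individual": panel.ids,
            "role": ["hybrid"] * n_hybrids + ["ilex"] * n_ilex + ["suber"] * n_suber,
        }
    )
    return panel, roles


def genotype_matrix_from_individuals(
    batches: Sequence[tuple[Individuals, str, str]],
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
    mothers: Mapping[str, str] | None = None,
) -> "GenotypeMatrix":
    """Assemble simulated individuals into an in-memory genotype matrix.

    ``batches`` pairs each individual batch with its (species, cohort)
    labels; seedlings take their mother id from ``mothers``. True
    genotypes are passed through unchanged (NULL stays visible), so the
    result mirrors a fully imputed call set rather than raw sequencer
    output — apply :func:`apply_observation_model` first to emulate the
    latter.
    """
    from hybridrad.core_data import GenotypeMatrix, Locus, SampleMeta

    L = batches[0][0].gt.shape[1]
    if chrom is None:
        chrom = np.asarray(["chr01"] * L, dtype=object)
    if pos is None:
        pos = np.arange(1, L + 1) * 100
    samples: list[SampleMeta] = []
    gts = []
    for ind, species, cohort in batches:
        for iid in ind.ids:
            samples.append(
                SampleMeta(
                    iid, species, cohort,
                    (mothers or {}).get(iid) if cohort == "seedling" else None,
                )
            )
        gts.append(ind.gt)
    gt = np.concatenate(gts, axis=0).transpose(1, 0, 2)
    loci = [
        Locus(chrom=str(c), pos=int(p), ref="A", alts=("C",), total_depth=None)
        for c, p in zip(chrom, pos)
    ]
    return GenotypeMatrix(loci=loci, samples=samples, gt=gt)


# ---------------------------------------------------------------------------
# whole-study simulation and serialization


@dataclass
class SimulatedStudy:
    """A full synthetic field study ready for the pipeline."""

    cfg: SimConfig
    pools: ParentalPools
    hybrid_adults: Individuals
    seedlings: Individuals
    seedling_truth: pd.DataFrame  # individual, mother, father_source, ...
    chrom: np.ndarray  # per-locus chromosome name
    pos: np.ndarray  # per-locus 1-based position
    is_indel: np.ndarray
    low_depth: np.ndarray  # per-locus bool: planted below the coverage filter

    def metadata(self) -> pd.DataFrame:
        rows = []
        for sp in ("ilex", "suber"):
            for iid in self.pools.adults[sp].ids:
                rows.append((iid, sp, "adult", "."))
        for iid in self.hybrid_adults.ids:
            rows.append((iid, "hybrid", "adult", "."))
        mothers = dict(zip(self.seedling_truth["individual"], self.seedling_truth["mother"]))
        for iid in self.seedlings.ids:
            rows.append((iid, "hybrid", "seedling", mothers[iid]))
        return pd.DataFrame(rows, columns=["sample", "species", "cohort", "mother"])

    def all_individuals(self) -> Individuals:
        return concat_individuals(
            [
                self.pools.adults["ilex"],
                self.pools.adults["suber"],
                self.hybrid_adults,
                self.seedlings,
            ]
        )

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for sp, exp in (("ilex", 0.0), ("suber", 1.0)):
            ind = self.pools.adults[sp]
            for iid, rh in zip(ind.ids, ind.realized_h()):
                rows.append((iid, f"pure_{sp}", exp, float(rh)))
        for iid, rh in zip(self.hybrid_adults.ids, self.hybrid_adults.realized_h()):
            rows.append((iid, "F1", 0.5, float(rh)))
        for (iid, rh, src, mrh) in zip(
            self.seedlings.ids,
            self.seedlings.realized_h(),
            self.seedling_truth["father_source"],
            self.seedling_truth["mother_realized_h"],
        ):
            father_h = {"suber": 1.0, "ilex": 0.0, "hybrid": 0.5}[src]
            rows.append((iid, f"OP_{src}", (float(mrh) + father_h) / 2.0, float(rh)))
        return pd.DataFrame(rows, columns=["individual", "category", "expected_h", "realized_h"])


def simulate_study(
    cfg: SimConfig = SimConfig(),
    family_sizes: Sequence[int] = DEFAULT_HYBRID_FAMILY_SIZES,
    pollen_cloud: Mapping[str, float] | None = None,
) -> SimulatedStudy:
    """Simulate the whole mixed-stand study under one seed.

    Adult hybrids are F1 individuals (the field adults were roughly F1).
    The first mothers among them carry open-pollinated families of the
    given sizes, fertilized from a pollen cloud biased toward cork oak
    (default weights suber 0.7 / ilex 0.3), matching the preferential
    backcrossing the q-ratio analysis is designed to detect.
    """
    rng = np.random.default_rng(cfg.seed)
    pools = simulate_parental_pools(cfg, rng)
    hybrid_adults = simulate_cross(
        pools.adults["ilex"], pools.adults["suber"], cfg.n_adult_hybrids, rng, prefix="HY"
    )
    if len(family_sizes) > cfg.n_adult_hybrids:
        raise ValueError("more families than adult hybrids")
    cloud = dict(pollen_cloud) if pollen_cloud else {"suber": 0.7, "ilex": 0.3}
    mothers = hybrid_adults.subset(range(len(family_sizes)))
    seedlings, truth = simulate_open_pollination(
        mothers,
        pools,
        hybrid_adults,
        family_sizes,
        cloud,
        rng,
        mother_ids=hybrid_adults.ids[: len(family_sizes)],
    )

    chrom, pos = _locus_coordinates(cfg, rng)
    is_indel = np.zeros(cfg.n_loci, dtype=bool)
    shared_idx = np.flatnonzero(pools.locus_class == "shared")
    n_indel = int(round(cfg.indel_fraction * cfg.n_loci))
    is_indel[shared_idx[:n_indel]] = True
    low_depth = np.zeros(cfg.n_loci, dtype=bool)
    if cfg.n_low_depth:
        low_depth[shared_idx[n_indel : n_indel + cfg.n_low_depth]] = True
    return SimulatedStudy(
        cfg=cfg,
        pools=pools,
        hybrid_adults=hybrid_adults,
        seedlings=seedlings,
        seedling_truth=truth,
        chrom=chrom,
        pos=pos,
        is_indel=is_indel,
        low_depth=low_depth,
    )


def _locus_coordinates(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Spread loci over chromosomes with sorted distinct random positions."""
    per_chrom = np.full(cfg.n_chroms, cfg.n_loci // cfg.n_chroms)
    per_chrom[: cfg.n_loci % cfg.n_chroms] += 1
    chroms = []
    poss = []
    for c, n_on_c in enumerate(per_chrom, start=1):
        length = max(200_000, n_on_c * 2_000)
        p = np.sort(rng.choice(np.arange(1, length), size=n_on_c, replace=False))
        chroms.extend([f"chr{c:02d}"] * n_on_c)
        poss.extend(p.tolist())
    return np.asarray(chroms, dtype=object), np.asarray(poss, dtype=np.int64)


def write_gene_annotation(study: SimulatedStudy, path: str | Path) -> None:
    """Toy GFF3: genes tile alternate 5 kb blocks of each chromosome, with
    the first 2.5 kb of each gene annotated as its single exon."""
    lines = ["##gff-version 3"]
    for c in range(1, study.cfg.n_chroms + 1):
        chrom = f"chr{c:02d}"
        on_c = study.pos[study.chrom == chrom]
        length = int(on_c.max()) + 5_000 if on_c.size else 200_000
        gene_no = 0
        for start in range(1, length, 10_000):
            gene_no += 1
            gid = f"G{chrom}_{gene_no}"
            end = start + 4_999
            lines.append(
                f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}"
            )
            lines.append(
                f"{chrom}\tsim\texon\t{start}\t{start + 2_499}\t.\t+\t.\t"
                f"ID={gid}.e1;Parent={gid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_anchor_table(study: SimulatedStudy, path: str | Path, cm_per_mb: float = 1.0) -> None:
    """Toy anchor table: three colinear anchors per chromosome/linkage group."""
    rows = []
    for c in range(1, study.cfg.n_chroms + 1):
        chrom = f"chr{c:02d}"
        on_c = study.pos[study.chrom == chrom]
        length = int(on_c.max()) + 5_000 if on_c.size else 200_000
        for bp in (1, length // 2, length):
            rows.append((chrom, bp, bp * cm_per_mb / 1e6))
    pd.DataFrame(rows, columns=["lg", "bp", "cM"]).to_csv(path, sep="\t", index=False)


def write_simulation(
    study: SimulatedStudy,
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
) -> dict[str, Path]:
    """Write the simulated study as pipeline-ready files.

    ``sim.vcf`` (observed genotypes with per-sample DP), ``meta.tsv``,
    ``truth.tsv``, ``genes.gff3`` and ``anchors.tsv``. Observation noise
    and read depths are drawn from a generator derived from the config
    seed, so a re-run with the same config is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = study.cfg
    rng = rng or np.random.default_rng(cfg.seed + 1_000)

    everyone = study.all_individuals()
    obs = apply_observation_model(everyone.gt, cfg.md_background, rng)
    called = obs[:, :, 0] != MISSING  # (n, L)

    lines = [
        "##fileformat=VCFv4.2",
        *(f"##contig=<ID=chr{c:02d}>" for c in range(1, cfg.n_chroms + 1)),
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(everyone.ids),
    ]
    n_ind = everyone.n
    for i in range(cfg.n_loci):
        ref, alt = ("A", "C") if not study.is_indel[i] else ("A", "AT")
        mean_dp = cfg.depth_mean_low if study.low_depth[i] else cfg.depth_mean
        dps = rng.poisson(mean_dp, size=n_ind)
        dps[~called[:, i]] = 0
        cells = []
        for j in range(n_ind):
            a, b = obs[j, i]
            gt_str = "./." if a == MISSING else f"{a}/{b}"
            cells.append(f"{gt_str}:{dps[j]}")
        lines.append(
            "\t".join(
                [
                    str(study.chrom[i]),
                    str(int(study.pos[i])),
                    ".",
                    ref,
                    alt,
                    ".",
                    ".",
                    f"DP={int(dps.sum())}",
                    "GT:DP",
                ]
                + cells
            )
        )
    paths = {
        "vcf": out_dir / "sim.vcf",
        "meta": out_dir / "meta.tsv",
        "truth": out_dir / "truth.tsv",
        "gff": out_dir / "genes.gff3",
        "anchors": out_dir / "anchors.tsv",
        "dropout": out_dir / "dropout_loci.tsv",
    }
    paths["vcf"].write_text("\n".join(lines) + "\n")
    study.metadata().to_csv(paths["meta"], sep="\t", index=False)
    study.truth_table().to_csv(paths["truth"], sep="\t", index=False)
    write_gene_annotation(study, paths["gff"])
    write_anchor_table(study, paths["anchors"])
    drop_rows = [
        {
            "locus": f"{study.chrom[i]}:{int(study.pos[i])}",
            "direction": "null_in_ilex"
            if study.pools.locus_class[i] == "dropout_ilex"
            else "null_in_suber",
        }
        for i in study.pools.dropout_locus_index()
    ]
    pd.DataFrame(drop_rows, columns=["locus", "direction"]).to_csv(
        paths["dropout"], sep="\t", index=False
    )
    return paths
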