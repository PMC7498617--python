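"""Introgression estimation: hybrid index and supervised two-population admixture.

All three estimators share one model. Given per-locus allele frequencies
in the two parental reference populations (adult *Q. ilex* and *Q. suber*
individuals only), an individual with suber genomic contribution
``h = q_s`` draws each of its allele copies independently from the mixture

    pi_h(a) = h * p_suber(a) + (1 - h) * p_ilex(a)

so an unordered genotype {a, b} has probability (2 - delta_ab) *
pi_h(a) * pi_h(b) under Hardy-Weinberg within the admixed pool. The
likelihood in h is log-concave, hence unimodal: direct maximization
(coarse grid plus golden-section refinement), EM over per-allele-copy
ancestry indicators, and the Gibbs posterior mean all agree on informative
data. Null alleles enter as ordinary alleles with their estimated parental
frequencies — this is what makes imputed dropout loci informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from hybridrad.core_data import MISSING, NULL, GenotypeMatrix, SampleMeta
from hybridrad.scenario_engine import PARENTAL_SPECIES, ScenarioResult

PSEUDO_DEFAULT = 0.5
GRID_DEFAULT = 1e-3


@dataclass(frozen=True)
class LocusFrequencies:
    """Allele frequencies of one locus in one population."""

    freqs: dict[int, float]  # allele code -> frequency (sums to 1)
    n_obs: int  # allele copies counted

    def get(self, allele: int) -> float:
        return self.freqs.get(allele, 0.0)


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies (NULL included) in each reference population.

    ``smoothed`` carries pseudo-count-regularized frequencies for
    likelihoods; ``raw`` carries plain count fractions for marker
    classification. Populations are keyed ``ilex`` / ``suber`` (and
    optionally ``hybrid`` for adult-hybrid pattern flags). Loci with no
    observed alleles in a parental population are listed in ``unusable``
    and skipped by the estimators.
    """

    locus_ids: list[str]
    smoothed: dict[str, dict[str, LocusFrequencies]]  # pop -> locus_id -> freqs
    raw: dict[str, dict[str, LocusFrequencies]]
    alleles: dict[str, list[int]]  # locus_id -> allele codes in play
    unusable: set[str]
    pseudo: float

    def usable_locus_ids(self) -> list[str]:
        return [lid for lid in self.locus_ids if lid not in self.unusable]


def _count_alleles(
    gt: np.ndarray, sample_idx: np.ndarray, alleles: Sequence[int]
) -> tuple[dict[int, int], int]:
    sub = gt[sample_idx].reshape(-1)
    sub = sub[sub != MISSING]
    counts = {a: int((sub == a).sum()) for a in alleles}
    return counts, int(sub.size)


def estimate_allele_frequencies(
    s: ScenarioResult | GenotypeMatrix,
    pseudo: float = PSEUDO_DEFAULT,
    include_hybrids: bool = False,
) -> AlleleFrequencyTable:
    """Estimate reference allele frequencies from adult parental individuals.

    MISSING genotypes are excluded from the counts; NULL is counted as an
    ordinary allele. Smoothed frequencies use a pseudo-count per allele
    symbol, ``freq(a) = (count(a) + pseudo) / (total + pseudo * k)`` with
    ``k`` the number of allele symbols at the locus; raw (pseudo = 0)
    frequencies are retained alongside. Seedlings never contribute;
    hybrids contribute only to the optional ``hybrid`` population used for
    marker classification.
    """
    m = s.matrix if isinstance(s, ScenarioResult) else s
    pops: dict[str, np.ndarray] = {
        sp: m.sample_indices(species=sp, cohort="adult") for sp in PARENTAL_SPECIES
    }
    for sp, idx in pops.items():
        if idx.size == 0:
            raise ValueError(f"no adult {sp} individuals to estimate frequencies from")
    if include_hybrids:
        pops["hybrid"] = m.sample_indices(species="hybrid", cohort="adult")

    locus_ids = m.locus_ids
    alleles_by_locus: dict[str, list[int]] = {}
    smoothed: dict[str, dict[str, LocusFrequencies]] = {p: {} for p in pops}
    raw: dict[str, dict[str, LocusFrequencies]] = {p: {} for p in pops}
    unusable: set[str] = set()

    for i, (lid, locus) in enumerate(zip(locus_ids, m.loci)):
        declared = list(range(locus.n_alleles))
        if np.any(m.gt[i] == NULL):
            declared = [NULL] + declared
        alleles_by_locus[lid] = declared
        k = len(declared)
        for pop, idx in pops.items():
            counts, total = _count_alleles(m.gt[i], idx, declared)
            if total == 0:
                raw[pop][lid] = LocusFrequencies(freqs={}, n_obs=0)
                smoothed[pop][lid] = LocusFrequencies(freqs={}, n_obs=0)
                if pop in PARENTAL_SPECIES:
                    unusable.add(lid)
                continue
            raw[pop][lid] = LocusFrequencies(
                freqs={a: c / total for a, c in counts.items()}, n_obs=total
            )
            denom = total + pseudo * k
            smoothed[pop][lid] = LocusFrequencies(
                freqs={a: (c + pseudo) / denom for a, c in counts.items()},
                n_obs=total,
            )
    return AlleleFrequencyTable(
        locus_ids=list(locus_ids),
        smoothed=smoothed,
        raw=raw,
        alleles=alleles_by_locus,
        unusable=unusable,
        pseudo=pseudo,
    )


@dataclass(frozen=True)
class AncestryEstimate:
    """Estimated suber genomic contribution of one individual."""

    sample_id: str
    q_s: float
    method: str  # hybrid_index_ml | admixture_em | admixture_gibbs
    loglik: float
    n_loci_used: int
    converged: bool = True
    iterations: int | None = None
    ci90: tuple[float, float] | None = None

    @property
    def q_ilex(self) -> float:
        return 1.0 - self.q_s


def _individual_observations(
    m: GenotypeMatrix, j: int, f: AlleleFrequencyTable
) -> tuple[np.ndarray, np.ndarray, int]:
    """Stack usable allele copies of sample ``j`` as (p_suber, p_ilex) arrays."""
    p_s, p_i = [], []
    n_loci = 0
    lids = m.locus_ids
    for i in range(m.n_loci):
        lid = lids[i]
        if lid in f.unusable:
            continue
        a, b = (int(x) for x in m.gt[i, j])
        if a == MISSING:
            continue
        fs = f.smoothed["suber"][lid]
        fi = f.smoothed["ilex"][lid]
        p_s.extend([fs.get(a), fs.get(b)])
        p_i.extend([fi.get(a), fi.get(b)])
        n_loci += 1
    return np.asarray(p_s), np.asarray(p_i), n_loci


def _loglik(h: float, p_s: np.ndarray, p_i: np.ndarray) -> float:
    pi = h * p_s + (1.0 - h) * p_i
    if np.any(pi <= 0):
        return -np.inf
    # genotype-constant terms (the 2 - delta factor) do not depend on h
    return float(np.log(pi).sum())


def hybrid_index_ml(
    m: GenotypeMatrix,
    j: int | str,
    f: AlleleFrequencyTable,
    grid: float = GRID_DEFAULT,
) -> AncestryEstimate:
    """Maximum-likelihood hybrid index of one individual.

    Maximizes the admixed-HWE log-likelihood over h in [0, 1] by a coarse
    grid at resolution ``grid`` refined with bounded golden-section
    search; ties break toward 0.5. MISSING loci and loci with undefined
    parental frequencies are skipped.
    """
    if isinstance(j, str):
        j = m.sample_index(j)
    p_s, p_i, n_loci = _individual_observations(m, j, f)
    if n_loci == 0:
        raise ValueError(
            f"sample {m.samples[j].sample_id!r}: zero usable loci for hybrid index"
        )
    hs = np.arange(0.0, 1.0 + grid / 2, grid)
    lls = np.array([_loglik(h, p_s, p_i) for h in hs])
    if not np.any(np.isfinite(lls)):
        raise ValueError(
            "log-likelihood is -inf everywhere; re-estimate frequencies with a "
            "positive pseudo-count"
        )
    best = np.flatnonzero(lls == lls.max())
    h0 = float(hs[best[np.argmin(np.abs(hs[best] - 0.5))]])
    lo, hi = max(0.0, h0 - grid), min(1.0, h0 + grid)
    res = minimize_scalar(
        lambda h: -_loglik(h, p_s, p_i),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    h_hat, ll = float(res.x), float(-res.fun)
    if _loglik(h0, p_s, p_i) > ll:  # golden section never beats the grid? keep best
        h_hat, ll = h0, _loglik(h0, p_s, p_i)
    return AncestryEstimate(
        sample_id=m.samples[j].sample_id,
        q_s=h_hat,
        method="hybrid_index_ml",
        loglik=ll,
        n_loci_used=n_loci,
    )


def admixture_em(
    m: GenotypeMatrix,
    f: AlleleFrequencyTable,
    samples: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> list[AncestryEstimate]:
    """Supervised two-population admixture proportions by EM.

    Parental frequencies are fixed (the supervised analogue of running a
    Bayesian clustering tool with K = 2 and reference populations). The
    E-step assigns each observed allele copy a responsibility
    ``w = h * p_S(a) / pi_h(a)`` of being suber-derived; the M-step sets h
    to the mean responsibility. The likelihood is the same unimodal
    function maximized by :func:`hybrid_index_ml`.
    """
    import warnings

    ids = samples if samples is not None else m.sample_ids
    out = []
    for sid in ids:
        j = m.sample_index(sid)
        p_s, p_i, n_loci = _individual_observations(m, j, f)
        if n_loci == 0:
            raise ValueError(f"sample {sid!r}: all loci MISSING or unusable")
        h = 0.5
        it = 0
        converged = False
        for it in range(1, max_iter + 1):
            pi = h * p_s + (1.0 - h) * p_i
            w = np.divide(h * p_s, pi, out=np.full_like(pi, 0.5), where=pi > 0)
            h_new = float(w.mean())
            if abs(h_new - h) < tol:
                h = h_new
                converged = True
                break
            h = h_new
        if not converged:
            warnings.warn(f"EM did not converge for {sid} in {max_iter} iterations")
        out.append(
            AncestryEstimate(
                sample_id=sid,
                q_s=h,
                method="admixture_em",
                loglik=_loglik(h, p_s, p_i),
                n_loci_used=n_loci,
                converged=converged,
                iterations=it,
            )
        )
    return out


def admixture_gibbs(
    m: GenotypeMatrix,
    f: AlleleFrequencyTable,
    samples: Sequence[str] | None = None,
    burn_in: int = 10_000,
    iters: int = 100_000,
    seed: int = 0,
    thin: int = 10,
) -> list[AncestryEstimate]:
    """Posterior mean admixture proportion by Gibbs sampling.

    Alternates per-allele-copy ancestry indicator draws with
    ``h ~ Beta(1 + n_suber, 1 + n_ilex)`` under a uniform prior. Defaults
    mirror a standard 10,000 burn-in / 100,000 iteration MCMC protocol;
    reduce both for test-scale runs. Reports the posterior mean and a 90%
    equal-tailed credible interval.
    """
    rng = np.random.default_rng(seed)
    ids = samples if samples is not None else m.sample_ids
    out = []
    for sid in ids:
        j = m.sample_index(sid)
        p_s, p_i, n_loci = _individual_observations(m, j, f)
        if n_loci == 0:
            raise ValueError(f"sample {sid!r}: all loci MISSING or unusable")
        h = 0.5
        kept = []
        n_copies = p_s.size
        for t in range(burn_in + iters):
            pi = h * p_s + (1.0 - h) * p_i
            w = np.divide(h * p_s, pi, out=np.full_like(pi, 0.5), where=pi > 0)
            z = rng.random(n_copies) < w
            n_sub = int(z.sum())
            h = float(rng.beta(1 + n_sub, 1 + n_copies - n_sub))
            if t >= burn_in and (t - burn_in) % thin == 0:
                kept.append(h)
        kept_arr = np.asarray(kept)
        q = float(kept_arr.mean())
        lo, hi = (float(x) for x in np.quantile(kept_arr, [0.05, 0.95]))
        out.append(
            AncestryEstimate(
                sample_id=sid,
                q_s=q,
                method="admixture_gibbs",
                loglik=_loglik(q, p_s, p_i),
                n_loci_used=n_loci,
                ci90=(lo, hi),
            )
        )
    return out


# ---------------------------------------------------------------------------
# family summaries and pollen-donor inference


def estimates_frame(estimates: Sequence[AncestryEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [e.sample_id for e in estimates],
            "q_s": [e.q_s for e in estimates],
            "method": [e.method for e in estimates],
            "loglik": [e.loglik for e in estimates],
            "n_loci": [e.n_loci_used for e in estimates],
        }
    )


def family_summaries(
    estimates: Sequence[AncestryEstimate], meta: Sequence[SampleMeta]
) -> pd.DataFrame:
    """Per-mother summaries of offspring q_s and of the ratio r = q_s(o)/q_s(m).

    One row per open-pollinated family: mean, sample standard deviation
    (ddof=1; reported as 0 and flagged for single-offspring families),
    max and min of the offspring q_s, and the same summaries of the
    offspring/mother ratio. Families without estimated offspring are
    omitted with a warning. Ratios require the mother's own q_s estimate;
    a mother with q_s = 0 has no defined ratio.
    """
    import warnings

    by_id = {e.sample_id: e for e in estimates}
    fams: dict[str, list[float]] = {}
    for smp in meta:
        if smp.cohort != "seedling" or smp.sample_id not in by_id:
            continue
        fams.setdefault(smp.mother_id, []).append(by_id[smp.sample_id].q_s)

    rows = []
    for mother_id, qs in sorted(fams.items()):
        if not qs:
            warnings.warn(f"family {mother_id}: no estimated offspring, omitted")
            continue
        arr = np.asarray(qs)
        single = arr.size == 1
        row = {
            "mother": mother_id,
            "n_offspring": arr.size,
            "q_s_mean": float(arr.mean()),
            "q_s_sd": 0.0 if single else float(arr.std(ddof=1)),
            "q_s_max": float(arr.max()),
            "q_s_min": float(arr.min()),
            "sd_degenerate": single,
        }
        mother_est = by_id.get(mother_id)
        if mother_est is not None:
            if mother_est.q_s == 0:
                raise ValueError(
                    f"mother {mother_id}: q_s = 0, offspring/mother ratio undefined"
                )
            r = arr / mother_est.q_s
            row.update(
                r_mean=float(r.mean()),
                r_max=float(r.max()),
                r_min=float(r.min()),
                q_s_mother=mother_est.q_s,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def classify_pollen_donor(r: float, epsilon: float = 0.0) -> str:
    """Read the pollen-donor species off an offspring/mother q_s ratio.

    Ratios above 1 point to fertilization by *Q. suber* (the offspring
    gained suber ancestry relative to its hybrid mother); below 1 to
    *Q. ilex*. ``epsilon`` widens the ambiguous band around 1.
    """
    if not r > 0:
        raise ValueError("ratio must be positive (mother q_s must be > 0)")
    if r > 1 + epsilon:
        return "suber"
    if r < 1 - epsilon:
        return "ilex"
    return "ambiguous"


def evaluate_accuracy(
    estimates: Sequence[AncestryEstimate],
    truth: pd.DataFrame,
) -> pd.DataFrame:
    """Per-pedigree-category accuracy of ancestry estimates.

    ``truth`` needs columns ``individual``, ``category`` and
    ``expected_h``. Returns one row per category with the mean and sd of
    the estimates, bias (mean - expected) and RMSE — the tabular form of
    a performance-versus-pedigree-class figure.
    """
    truth_idx = truth.set_index("individual")
    rows = []
    for e in estimates:
        if e.sample_id not in truth_idx.index:
            raise ValueError(f"estimated sample {e.sample_id!r} missing from truth")
        t = truth_idx.loc[e.sample_id]
        rows.append(
            {
                "category": t["category"],
                "expected_h": float(t["expected_h"]),
                "q_s": e.q_s,
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for (cat, exp_h), grp in df.groupby(["category", "expected_h"], sort=False):
        q = grp["q_s"].to_numpy()
        out.append(
            {
                "category": cat,
                "expected_h": exp_h,
                "n": q.size,
                "mean_q_s": float(q.mean()),
                "sd_q_s": float(q.std(ddof=1)) if q.size > 1 else 0.0,
                "bias": float(q.mean() - exp_h),
                "rmse": float(np.sqrt(np.mean((q - exp_h) ** 2))),
            }
        )
    return pd.DataFrame(out).sort_values("expected_h").reset_index(drop=True)
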