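"""Marker diagnosticity flags and per-scenario marker-database export.

Classifies loci by their raw allele-frequency patterns in the adult
reference populations: *discriminant* loci have a near-fixed major allele
in one species that is rare in the other; *hybrid-pattern* loci look like
one parental species in the adult hybrids and very unlike the other;
*high-imputed-frequency* loci are imputed dropout loci whose null allele
is unexpectedly common in adult hybrids (a candidate methylation
signature). All flags are functions of frequencies only.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from hybridrad.core_data import NULL
from hybridrad.ancestry import AlleleFrequencyTable
from hybridrad.scenario_engine import ScenarioResult

HI_DEFAULT = 0.9
LO_DEFAULT = 0.2
DELTA_SIM_DEFAULT = 0.1
DELTA_DIFF_DEFAULT = 0.5
HIGH_IMPUTED_FREQ_DEFAULT = 0.75


@dataclass
class MarkerFlags:
    """Per-locus marker classification flags."""

    is_imputed: dict[str, bool]
    is_discriminant: dict[str, bool]
    hybrid_pattern: dict[str, str]  # ilex_like | suber_like | none
    high_imputed_freq_in_hybrids: dict[str, bool]
    reasons: dict[str, str]  # locus_id -> why a flag could not be evaluated


def _new_flags(locus_ids) -> MarkerFlags:
    return MarkerFlags(
        is_imputed={lid: False for lid in locus_ids},
        is_discriminant={lid: False for lid in locus_ids},
        hybrid_pattern={lid: "none" for lid in locus_ids},
        high_imputed_freq_in_hybrids={lid: False for lid in locus_ids},
        reasons={},
    )


def flag_discriminant(
    f: AlleleFrequencyTable,
    hi: float = HI_DEFAULT,
    lo: float = LO_DEFAULT,
    flags: MarkerFlags | None = None,
) -> MarkerFlags:
    """Flag loci whose most common allele separates the parental species.

    A locus is discriminant iff the most common allele in one species has
    raw frequency >= ``hi`` there and <= ``lo`` in the other species
    (inclusive bounds, evaluated in both orientations — the flag is
    symmetric in species). Imputed dropout loci qualify through the NULL
    allele like any other. Loci with undefined frequencies in either
    species are left unflagged with a recorded reason.
    """
    flags = flags or _new_flags(f.locus_ids)
    for lid in f.locus_ids:
        fi = f.raw["ilex"].get(lid)
        fs = f.raw["suber"].get(lid)
        if fi is None or fs is None or fi.n_obs == 0 or fs.n_obs == 0:
            flags.reasons[lid] = "frequencies undefined in a parental population"
            continue
        hit = False
        for high_pop, low_pop in ((fs, fi), (fi, fs)):
            major, p = max(high_pop.freqs.items(), key=lambda kv: (kv[1], -kv[0]))
            if p >= hi and low_pop.get(major) <= lo:
                hit = True
                break
        flags.is_discriminant[lid] = hit
    return flags


def flag_hybrid_pattern(
    f: AlleleFrequencyTable,
    delta_sim: float = DELTA_SIM_DEFAULT,
    delta_diff: float = DELTA_DIFF_DEFAULT,
    flags: MarkerFlags | None = None,
) -> MarkerFlags:
    """Flag loci whose adult-hybrid frequencies mimic one parental species.

    Distance between two frequency vectors is the maximum absolute
    per-allele difference. With d_I = d(hybrid, ilex) and d_S = d(hybrid,
    suber): ``ilex_like`` iff d_I <= delta_sim and d_S >= delta_diff;
    ``suber_like`` symmetric; otherwise ``none`` (the expected outcome for
    an F1-intermediate locus). Requires the frequency table to carry an
    adult-hybrid population.
    """
    if "hybrid" not in f.raw:
        raise ValueError(
            "frequency table has no adult-hybrid population; re-estimate with "
            "include_hybrids=True"
        )
    flags = flags or _new_flags(f.locus_ids)
    for lid in f.locus_ids:
        fh = f.raw["hybrid"].get(lid)
        fi = f.raw["ilex"].get(lid)
        fs = f.raw["suber"].get(lid)
        if any(x is None or x.n_obs == 0 for x in (fh, fi, fs)):
            continue
        alleles = set(fh.freqs) | set(fi.freqs) | set(fs.freqs)
        d_i = max(abs(fh.get(a) - fi.get(a)) for a in alleles)
        d_s = max(abs(fh.get(a) - fs.get(a)) for a in alleles)
        if d_i <= delta_sim and d_s >= delta_diff:
            flags.hybrid_pattern[lid] = "ilex_like"
        elif d_s <= delta_sim and d_i >= delta_diff:
            flags.hybrid_pattern[lid] = "suber_like"
    return flags


def flag_high_imputed_frequency(
    f: AlleleFrequencyTable,
    imputed: Mapping[str, str] | set,
    threshold: float = HIGH_IMPUTED_FREQ_DEFAULT,
    flags: MarkerFlags | None = None,
) -> MarkerFlags:
    """Flag imputed loci whose NULL allele is common among adult hybrids.

    An imputed locus is flagged iff the raw NULL-allele frequency among
    adult hybrids is >= ``threshold``. Non-imputed loci are never flagged
    (the flag implies imputation by construction).
    """
    if "hybrid" not in f.raw:
        raise ValueError(
            "frequency table has no adult-hybrid population; re-estimate with "
            "include_hybrids=True"
        )
    flags = flags or _new_flags(f.locus_ids)
    for lid in f.locus_ids:
        flags.is_imputed[lid] = lid in imputed
        if lid not in imputed:
            continue
        fh = f.raw["hybrid"].get(lid)
        if fh is None or fh.n_obs == 0:
            continue
        flags.high_imputed_freq_in_hybrids[lid] = fh.get(NULL) >= threshold
    return flags


def flag_all(
    f: AlleleFrequencyTable,
    imputed: Mapping[str, str] | set,
    hi: float = HI_DEFAULT,
    lo: float = LO_DEFAULT,
    delta_sim: float = DELTA_SIM_DEFAULT,
    delta_diff: float = DELTA_DIFF_DEFAULT,
    threshold: float = HIGH_IMPUTED_FREQ_DEFAULT,
) -> MarkerFlags:
    flags = _new_flags(f.locus_ids)
    flag_discriminant(f, hi=hi, lo=lo, flags=flags)
    if "hybrid" in f.raw:
        flag_hybrid_pattern(f, delta_sim=delta_sim, delta_diff=delta_diff, flags=flags)
        flag_high_imputed_frequency(f, imputed, threshold=threshold, flags=flags)
    else:
        for lid in f.locus_ids:
            flags.is_imputed[lid] = lid in imputed
    return flags


def marker_table(
    s: ScenarioResult,
    flags: MarkerFlags,
    f: AlleleFrequencyTable | None = None,
    annotations: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One row per locus of the scenario: coordinates, classes, flags, frequencies."""
    rows = []
    for locus in s.matrix.loci:
        lid = locus.locus_id
        row = {
            "locus": lid,
            "chrom": locus.chrom,
            "pos": locus.pos,
            "variant_type": locus.variant_type,
            "region": locus.region,
            "fragment_id": locus.fragment_id or "unassigned",
            "is_imputed": flags.is_imputed.get(lid, False),
            "is_discriminant": flags.is_discriminant.get(lid, False),
            "hybrid_pattern": flags.hybrid_pattern.get(lid, "none"),
            "high_imputed_freq_in_hybrids": flags.high_imputed_freq_in_hybrids.get(
                lid, False
            ),
            "annotation": (annotations or {}).get(lid, ""),
        }
        if f is not None:
            for pop in f.raw:
                lf = f.raw[pop].get(lid)
                row[f"freq_null_{pop}"] = (
                    lf.get(NULL) if lf is not None and lf.n_obs else float("nan")
                )
                row[f"n_obs_{pop}"] = lf.n_obs if lf is not None else 0
        rows.append(row)
    cols = [
        "locus", "chrom", "pos", "variant_type", "region", "fragment_id",
        "is_imputed", "is_discriminant", "hybrid_pattern",
        "high_imputed_freq_in_hybrids", "annotation",
    ]
    if f is not None:
        for pop in f.raw:
            cols += [f"freq_null_{pop}", f"n_obs_{pop}"]
    return pd.DataFrame(rows, columns=cols)


def export_marker_database(
    s: ScenarioResult,
    flags: MarkerFlags,
    path: str | Path,
    f: AlleleFrequencyTable | None = None,
    annotations: Mapping[str, str] | None = None,
    sqlite_mirror: bool = False,
) -> pd.DataFrame:
    """Write the per-scenario marker database.

    Canonical form is a delimited-text table (TSV); ``sqlite_mirror``
    additionally writes a single-table relational mirror next to it. The
    returned frame has exactly one row per locus of the scenario.
    """
    df = marker_table(s, flags, f=f, annotations=annotations)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    if sqlite_mirror:
        db_path = path.with_suffix(".sqlite")
        with sqlite3.connect(db_path) as con:
            df.to_sql("markers", con, if_exists="replace", index=False)
    return df


def summary_counts(df: pd.DataFrame) -> dict[str, int]:
    """Tallies of the marker database: totals partition into imputed + unimputed."""
    n_total = len(df)
    n_imputed = int(df["is_imputed"].sum())
    return {
        "n_total": n_total,
        "n_imputed": n_imputed,
        "n_unimputed": n_total - n_imputed,
        "n_discriminant": int(df["is_discriminant"].sum()),
        "n_ilex_like": int((df["hybrid_pattern"] == "ilex_like").sum()),
        "n_suber_like": int((df["hybrid_pattern"] == "suber_like").sum()),
        "n_high_imputed_freq": int(df["high_imputed_freq_in_hybrids"].sum()),
    }
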