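"""Linkage-group anchoring of markers via per-group linear bp -> cM maps.

Marker positions come from homology hits of flanking sequences against a
chromosome-level relative's genome; a per-linkage-group ordinary
least-squares line fitted on anchor SNPs (known bp and cM) converts hit
coordinates into genetic positions. The module consumes standard
12-column tabular hit files and never runs the homology search itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from hybridrad.core_data import Locus

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def extract_flanks(
    reference: str | Path,
    loci: Sequence[Locus],
    width: int = 200,
    out_path: str | Path | None = None,
) -> list[tuple[str, str]]:
    """Extract per-locus flanking sequences (width bp each side) from a FASTA.

    Each record covers up to ``2 * width + 1`` bases centered on the locus
    position, truncated at sequence ends; the record id encodes the locus
    id. Loci on sequences absent from the reference are skipped with a
    warning. Returns (id, sequence) pairs and optionally writes multi-FASTA.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(reference))
    records: list[tuple[str, str]] = []
    for locus in loci:
        if locus.chrom not in fa:
            warnings.warn(
                f"sequence {locus.chrom!r} absent from reference; "
                f"locus {locus.locus_id} skipped"
            )
            continue
        seq = fa[locus.chrom]
        start = max(0, locus.pos - 1 - width)  # 0-based inclusive
        end = min(len(seq), locus.pos + width)  # 0-based exclusive
        records.append((locus.locus_id, str(seq[start:end])))
    if out_path is not None:
        with open(out_path, "w") as fh:
            for rid, s in records:
                fh.write(f">{rid}\n{s}\n")
    return records


@dataclass(frozen=True)
class GroupMap:
    """OLS bp -> cM line of one linkage group."""

    linkage_group: str
    slope: float  # cM per bp
    intercept: float  # cM
    r2: float
    bp_min: int
    bp_max: int

    def predict(self, bp: float, extrapolate: bool = False) -> float:
        if not extrapolate and not (self.bp_min <= bp <= self.bp_max):
            raise ValueError(
                f"bp {bp} outside anchor span [{self.bp_min}, {self.bp_max}] "
                f"of {self.linkage_group}; pass extrapolate=True to override"
            )
        return self.slope * bp + self.intercept

    @property
    def span_mb(self) -> float:
        return (self.bp_max - self.bp_min) / 1e6


@dataclass
class LinearMap:
    """Collection of per-linkage-group maps."""

    groups: dict[str, GroupMap]

    def __getitem__(self, lg: str) -> GroupMap:
        return self.groups[lg]

    def __contains__(self, lg: str) -> bool:
        return lg in self.groups


def read_anchor_table(path: str | Path) -> pd.DataFrame:
    """Read an anchor TSV ``lg<TAB>bp<TAB>cM``."""
    df = pd.read_csv(path, sep="\t", dtype={"lg": str})
    required = {"lg", "bp", "cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"anchor table needs columns {sorted(required)}")
    if (df["bp"] < 1).any() or (df["cM"] < 0).any():
        raise ValueError("anchors require bp >= 1 and cM >= 0")
    return df


def fit_bp_to_cm(anchors: pd.DataFrame) -> LinearMap:
    """Fit an ordinary least-squares cM-on-bp line per linkage group.

    Groups with fewer than two distinct-bp anchors cannot be fitted and
    are excluded with a warning. r-squared is reported per group (defined
    as 1 when the anchor cM values have zero variance and the fit is exact).
    """
    groups: dict[str, GroupMap] = {}
    for lg, grp in anchors.groupby("lg", sort=True):
        bp = grp["bp"].to_numpy(dtype=float)
        cm = grp["cM"].to_numpy(dtype=float)
        if len(grp) < 2 or np.unique(bp).size < 2:
            warnings.warn(f"linkage group {lg}: <2 distinct-bp anchors, unfittable")
            continue
        res = stats.linregress(bp, cm)
        r2 = 1.0 if np.allclose(np.std(cm), 0) else float(res.rvalue**2)
        groups[str(lg)] = GroupMap(
            linkage_group=str(lg),
            slope=float(res.slope),
            intercept=float(res.intercept),
            r2=r2,
            bp_min=int(bp.min()),
            bp_max=int(bp.max()),
        )
    return LinearMap(groups=groups)


def read_blast6(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular homology hit file (outfmt-6 layout)."""
    return pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, dtype={"sseqid": str})


def place_markers(
    hits: pd.DataFrame,
    maps: LinearMap,
    group_of_target: Mapping[str, str] | None = None,
    evalue_max: float | None = None,
    extrapolate: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place each marker on a linkage group from its best homology hit.

    The best hit per marker is the lowest e-value (ties broken by lowest
    target bp, then target id). The hit's target is mapped to a linkage
    group either directly by name or through ``group_of_target``; the
    fitted line converts the target start coordinate to cM. Markers whose
    best hit falls on an unmapped target or an unfitted group are listed
    as unplaced, as are markers with no hit surviving ``evalue_max``.

    Returns ``(placements, per-group stats)`` where stats carry marker
    counts and density = count / anchor bp span in Mb.
    """
    hits = hits.copy()
    if evalue_max is not None:
        hits = hits[hits["evalue"] <= evalue_max]
    hits["lg"] = (
        hits["sseqid"].map(group_of_target) if group_of_target else hits["sseqid"]
    )

    placements = []
    unplaced = []
    for qid, grp in hits.groupby("qseqid", sort=True):
        grp = grp.sort_values(
            ["evalue", "sstart", "sseqid"], kind="mergesort"
        )
        best = grp.iloc[0]
        lg = best["lg"]
        if pd.isna(lg) or lg not in maps:
            unplaced.append({"marker": qid, "reason": "target not on a fitted group"})
            continue
        cm = maps[lg].predict(float(best["sstart"]), extrapolate=extrapolate)
        placements.append(
            {
                "marker": qid,
                "lg": lg,
                "bp": int(best["sstart"]),
                "cM": cm,
                "evalue": float(best["evalue"]),
            }
        )
    placed_df = pd.DataFrame(
        placements, columns=["marker", "lg", "bp", "cM", "evalue"]
    )
    unplaced_df = pd.DataFrame(unplaced, columns=["marker", "reason"])
    return placed_df, unplaced_df


def group_stats(placed: pd.DataFrame, maps: LinearMap) -> pd.DataFrame:
    """Per-linkage-group marker count and density (markers per Mb of anchor span)."""
    rows = []
    for lg in sorted(maps.groups):
        sub = placed[placed["lg"] == lg]
        span = maps[lg].span_mb
        rows.append(
            {
                "lg": lg,
                "n_markers": len(sub),
                "span_mb": span,
                "density_per_mb": len(sub) / span if span > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
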