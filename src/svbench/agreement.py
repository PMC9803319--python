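"""Between-caller agreement via the sets of protein-coding genes SVs span.

Without a ground truth for real samples, callsets from different callers are
compared by which genes their predictions cover: a gene counts as spanned when
at least 50% of its length is covered by a single SV, SVs larger than 50 kbp
are excluded (beyond that size even assembly-based calls are unreliable), and
two predictions of the same SV type agree iff they span exactly the same set
of genes.  Concordance across callers is summarized with UpSet-style exclusive
intersection counts of the per-caller gene-set unions, per-caller unique-gene
percentages, and per-strain median counts.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, overlap_length
from .variants import SV_TYPES, StructuralVariant, SvCallSet

__all__ = [
    "GeneModel",
    "GeneSpanAssignment",
    "CallerGeneSets",
    "load_protein_coding_genes",
    "genes_spanned_by_sv",
    "caller_gene_sets",
    "agreement_match",
    "upset_counts",
    "unique_fraction",
    "per_strain_summary",
]

#: Default size cut above which SVs are excluded from gene-span comparisons.
MAX_SV_SIZE = 50_000
#: Default minimum fraction of a gene's length an SV must cover.
MIN_GENE_COV = 0.5


@dataclass(frozen=True)
class GeneModel:
    """A gene span with a stable identifier and biotype."""

    gene_id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"


@dataclass(frozen=True)
class GeneSpanAssignment:
    """One prediction and the genes it covers >= the coverage threshold."""

    variant: StructuralVariant
    gene_ids: frozenset[str]


@dataclass
class CallerGeneSets:
    """Per-caller gene-set unions and per-variant signatures for one SV type."""

    sv_type: str
    unions: dict[str, frozenset[str]] = field(default_factory=dict)
    signatures: dict[str, list[GeneSpanAssignment]] = field(default_factory=dict)

    @property
    def callers(self) -> list[str]:
        return sorted(self.unions)


def load_protein_coding_genes(
    gff3_path: str | Path, biotypes: Sequence[str] = ("protein_coding",)
) -> list[GeneModel]:
    """Load protein-coding gene spans from a GFF3 annotation.

    Gene features are taken from ``gene`` records whose ``biotype`` (or
    ``gene_biotype``/``gene_type``) attribute is in ``biotypes``; 1-based
    inclusive GFF3 coordinates become 0-based half-open intervals.
    """
    with open(gff3_path) as fh:  # gffutils refuses feature-less files
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils wraps the offending line in its message
        raise ValueError(f"malformed GFF3 {gff3_path}: {exc}") from exc
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        biotype = None
        for key in ("biotype", "gene_biotype", "gene_type"):
            if key in feat.attributes:
                biotype = feat.attributes[key][0]
                break
        if biotype not in biotypes:
            continue
        gene_id = feat.id
        if "gene_id" in feat.attributes:
            gene_id = feat.attributes["gene_id"][0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(feat.seqid, feat.start - 1, feat.end),
                biotype=biotype,
            )
        )
    return genes


def _gene_tree(genes: Iterable[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g
        )
    return trees


def genes_spanned_by_sv(
    v: StructuralVariant,
    genes: Sequence[GeneModel] | Mapping[str, IntervalTree],
    min_cov: float = MIN_GENE_COV,
    max_sv_size: int = MAX_SV_SIZE,
) -> frozenset[str]:
    """Gene IDs whose span is covered >= ``min_cov`` by this single SV.

    Returns the empty set when the SV exceeds ``max_sv_size`` (size-excluded).
    Coverage is purely positional; strand is ignored.
    """
    if v.size > max_sv_size:
        return frozenset()
    trees = genes if isinstance(genes, Mapping) else _gene_tree(genes)
    hits = set()
    for node in trees.get(v.chrom, IntervalTree()).overlap(
        v.interval.start, v.interval.end
    ):
        g: GeneModel = node.data
        if overlap_length(v.interval, g.interval) / g.interval.length >= min_cov:
            hits.add(g.gene_id)
    return frozenset(hits)


def caller_gene_sets(
    callsets: Mapping[str, SvCallSet],
    genes: Sequence[GeneModel],
    sv_type: str,
    min_cov: float = MIN_GENE_COV,
    max_sv_size: int = MAX_SV_SIZE,
) -> CallerGeneSets:
    """Per-caller gene-set unions and per-variant signatures for one SV type.

    Variants whose gene set is empty (no gene covered >= min_cov, or
    size-excluded) are dropped from the agreement analysis.
    """
    trees = _gene_tree(genes)
    out = CallerGeneSets(sv_type=sv_type)
    for caller, cs in callsets.items():
        assignments = []
        for v in cs.of_type(sv_type):
            gene_ids = genes_spanned_by_sv(
                v, trees, min_cov=min_cov, max_sv_size=max_sv_size
            )
            if gene_ids:
                assignments.append(GeneSpanAssignment(variant=v, gene_ids=gene_ids))
        union: frozenset[str] = frozenset().union(*(a.gene_ids for a in assignments)) \
            if assignments else frozenset()
        out.unions[caller] = union
        out.signatures[caller] = assignments
    return out


def agreement_match(a: GeneSpanAssignment, b: GeneSpanAssignment) -> bool:
    """Two predictions agree iff same SV type and exactly the same gene set."""
    if not a.gene_ids or not b.gene_ids:
        raise ValueError("agreement is defined only for non-empty gene sets")
    return a.variant.sv_type == b.variant.sv_type and a.gene_ids == b.gene_ids


def upset_counts(
    sets: CallerGeneSets | Mapping[str, frozenset[str] | set[str]],
    top_k: Optional[int] = None,
) -> dict[frozenset[str], int]:
    """Exclusive intersection counts over every non-empty caller combination.

    UpSet semantics: a gene contributes to exactly the combination of callers
    that contain it, so the counts partition the union of all caller sets.
    ``top_k`` keeps only the K largest combinations (for plotting-style
    truncation).
    """
    unions = sets.unions if isinstance(sets, CallerGeneSets) else dict(sets)
    if not unions:
        raise ValueError("need at least one caller")
    counts: dict[frozenset[str], int] = {}
    all_genes = set().union(*unions.values()) if unions else set()
    for gene in all_genes:
        combo = frozenset(c for c, genes in unions.items() if gene in genes)
        counts[combo] = counts.get(combo, 0) + 1
    if top_k is not None:
        top = sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0])))[:top_k]
        counts = dict(top)
    return counts


def unique_fraction(
    sets: CallerGeneSets | Mapping[str, frozenset[str] | set[str]], caller: str
) -> Optional[float]:
    """Percentage of this caller's genes found in no other caller's set.

    Returns None (absent) when the caller's gene set is empty.
    """
    unions = sets.unions if isinstance(sets, CallerGeneSets) else dict(sets)
    if caller not in unions:
        raise KeyError(f"unknown caller {caller!r}; have {sorted(unions)}")
    mine = unions[caller]
    if not mine:
        return None
    others = set().union(*(g for c, g in unions.items() if c != caller)) \
        if len(unions) > 1 else set()
    return 100.0 * len(mine - others) / len(mine)


def per_strain_summary(
    callsets: Mapping[tuple[str, str], SvCallSet],
    genes: Sequence[GeneModel],
    sv_types: Sequence[str] = SV_TYPES,
    min_cov: float = MIN_GENE_COV,
    max_sv_size: int = MAX_SV_SIZE,
) -> pd.DataFrame:
    """Median per-strain variant and distinct-gene counts, per caller and type.

    ``callsets`` maps (strain, caller) to a normalized callset.  For each
    caller and SV type the median across strains of (a) the variant count and
    (b) the number of distinct genes spanned is reported; even strain counts
    use the mean of the two middle values, so medians can be half-integers.
    """
    trees = _gene_tree(genes)
    rows = []
    callers = sorted({caller for _, caller in callsets})
    strains = sorted({strain for strain, _ in callsets})
    for caller in callers:
        for sv_type in sv_types:
            n_variants = []
            n_genes = []
            for strain in strains:
                cs = callsets.get((strain, caller))
                if cs is None:
                    continue
                typed = cs.of_type(sv_type)
                n_variants.append(len(typed))
                spanned: set[str] = set()
                for v in typed:
                    spanned |= genes_spanned_by_sv(
                        v, trees, min_cov=min_cov, max_sv_size=max_sv_size
                    )
                n_genes.append(len(spanned))
            if not n_variants:
                continue
            rows.append(
                {
                    "caller": caller,
                    "sv_type": sv_type,
                    "n_strains": len(n_variants),
                    "median_variants": statistics.median(n_variants),
                    "median_genes": statistics.median(n_genes),
                }
            )
    return pd.DataFrame(rows)
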