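"""Peak-to-gene assignment, upstream/intragenic classification, and the
distance-to-TSS vs intensity trend.

The assignment rule: a summit inside exactly one gene body is intragenic
for that gene (positive oriented distance from the TSS); otherwise the
nearest gene whose TSS lies downstream of the summit in that gene's
orientation, within the upstream window, claims it as an upstream
(promoter) peak with negative distance; failing both, the gene with the
overall nearest TSS is assigned. Ties break to the smaller absolute
distance, then lexicographic gene id. The upstream window (default 500 bp)
is the one genuinely free parameter — upstream/intragenic counts depend
on it directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .synthetic import GeneModel, circular_distance
from .consolidate import ConsolidatedTarget, _permutation_pvalue


@dataclass(frozen=True)
class TargetAnnotation:
    gene_id: str
    distance_to_tss: int  # oriented; negative = upstream of the TSS
    location_class: str   # "upstream" | "intragenic"


def oriented_offset(summit: int, gene: GeneModel, length: int,
                    circular: bool) -> int:
    """Signed offset from the TSS in the gene's reading direction:
    positive downstream (into/past the gene), negative upstream."""
    if gene.strand == "+":
        off = summit - gene.tss
    else:
        off = gene.tss - summit
    if circular:
        off %= length
        if off > length // 2:
            off -= length
    return int(off)


def assign_target(summit: int, genes: Sequence[GeneModel],
                  genome_length: int, upstream_window: int = 500,
                  circular: bool = True) -> TargetAnnotation:
    """Assign one summit to a gene and classify its location."""
    if not genes:
        raise ValueError("empty gene list")
    summit = summit % genome_length if circular else summit

    inside = [g for g in genes if g.start <= summit < g.end]
    if inside:
        g = min(inside, key=lambda g: (abs(oriented_offset(
            summit, g, genome_length, circular)), g.gene_id))
        return TargetAnnotation(g.gene_id,
                                oriented_offset(summit, g, genome_length,
                                                circular), "intragenic")

    upstream = []
    for g in genes:
        off = oriented_offset(summit, g, genome_length, circular)
        if -upstream_window <= off < 0:
            upstream.append((abs(off), g.gene_id, g, off))
    if upstream:
        _, _, g, off = min(upstream)
        return TargetAnnotation(g.gene_id, off, "upstream")

    # fallback: nearest TSS overall (unoriented circular distance)
    g = min(genes, key=lambda g: (circular_distance(summit, g.tss,
                                                    genome_length)
                                  if circular else abs(summit - g.tss),
                                  g.gene_id))
    return TargetAnnotation(g.gene_id,
                            oriented_offset(summit, g, genome_length,
                                            circular), "upstream")


def annotate_targets(targets: Sequence[ConsolidatedTarget],
                     genes: Sequence[GeneModel], genome_length: int,
                     upstream_window: int = 500,
                     circular: bool = True) -> list:
    """Fill gene_id / distance_to_tss / location_class on each target."""
    out = []
    for t in targets:
        ann = assign_target(t.locus, genes, genome_length, upstream_window,
                            circular)
        out.append(replace(t, gene_id=ann.gene_id,
                           distance_to_tss=ann.distance_to_tss,
                           location_class=ann.location_class))
    return out


def classify_counts(annotations: Sequence) -> tuple:
    """(n_upstream, n_intragenic); partitions the input."""
    n_up = sum(1 for a in annotations
               if getattr(a, "location_class", None) == "upstream")
    n_in = sum(1 for a in annotations
               if getattr(a, "location_class", None) == "intragenic")
    return n_up, n_in


def distance_intensity_trend(targets: Sequence[ConsolidatedTarget],
                             method: str = "spearman",
                             n_perm: int = 10_000, seed: int = 0):
    """Correlation of |distance to TSS| with peak intensity.

    A negative coefficient means promoter-proximal peaks are stronger.
    Returns (coefficient, permutation p-value); (nan, nan) when either
    variable has zero variance.
    """
    annotated = [t for t in targets if t.distance_to_tss is not None]
    if len(annotated) < 3:
        raise ValueError("need >= 3 annotated targets")
    d = np.array([abs(t.distance_to_tss) for t in annotated], dtype=float)
    i = np.array([t.max_intensity() for t in annotated], dtype=float)
    return _permutation_pvalue(d, i, method, n_perm, seed)


# ---------------------------------------------------------------------------
# GFF3 input
# ---------------------------------------------------------------------------

def read_gff3(path, feature_type: str = "gene") -> list:
    """Read ``gene`` features (1-based inclusive) into 0-based half-open
    GeneModel records via gffutils."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for f in db.features_of_type(feature_type, order_by="start"):
        gid = f.attributes.get("ID", [f.id])[0]
        genes.append(GeneModel(gid, f.start - 1, f.end, f.strand))
    return genes
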