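"""Replicate merging, reproducibility correlation, regulon comparison.

Peaks called independently per replicate are clustered into consolidated
binding targets by single-linkage on summit position (circular distance).
A target's *support* n is the number of replicates in which a significant
peak was found — significance here meaning presence in that replicate's
filtered peak set. Absent replicates contribute intensity 0, so
condition-specific binding shows up as blocks in the Pearson matrix rather
than being discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import PeakSet
from .synthetic import circular_distance


@dataclass
class ConsolidatedTarget:
    locus: int
    support: int
    per_sample_intensity: dict
    condition_presence: dict
    gene_id: str | None = None
    distance_to_tss: int | None = None
    location_class: str | None = None
    regulator: str = ""

    def max_intensity(self) -> float:
        return max(self.per_sample_intensity.values(), default=0.0)

    def conditions_present(self) -> frozenset:
        return frozenset(c for c, v in self.condition_presence.items() if v)


# ---------------------------------------------------------------------------
# replicate merging
# ---------------------------------------------------------------------------

def merge_replicates(peaksets: Sequence[PeakSet],
                     merge_distance: float | None = None) -> list:
    """Single-linkage clustering of summits across samples.

    Summits closer than ``merge_distance`` (default: expected_width / 2,
    circular distance) chain into one cluster; each cluster becomes one
    target with an intensity-weighted mean locus. Permutation-invariant in
    the order of the peak sets.
    """
    if not peaksets:
        return []
    lengths = {ps.genome_length for ps in peaksets}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent genome lengths: {sorted(lengths)}")
    L = lengths.pop()
    circular = True
    if merge_distance is None:
        merge_distance = max(ps.expected_width for ps in peaksets) / 2.0

    entries = []  # (summit, intensity, sample, condition)
    all_samples = []
    conditions = []
    for ps in peaksets:
        if ps.sample not in all_samples:
            all_samples.append(ps.sample)
        if ps.condition not in conditions:
            conditions.append(ps.condition)
        for p in ps.peaks:
            w = p.norm_intensity if p.norm_intensity is not None else p.score
            entries.append((p.summit % L, float(w), ps.sample, ps.condition))
    if not entries:
        return []
    entries.sort(key=lambda t: (t[0], t[2]))

    # split sorted summits at gaps > merge_distance; re-join across origin
    clusters = [[entries[0]]]
    for e in entries[1:]:
        if e[0] - clusters[-1][-1][0] <= merge_distance:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    if circular and len(clusters) > 1:
        wrap_gap = (clusters[0][0][0] + L) - clusters[-1][-1][0]
        if wrap_gap <= merge_distance:
            # shift first cluster past the origin and append to the last
            shifted = [(s + L, w, sm, c) for s, w, sm, c in clusters[0]]
            clusters[-1].extend(shifted)
            clusters = clusters[1:]

    targets = []
    for cl in clusters:
        summits = np.array([c[0] for c in cl], dtype=float)
        weights = np.array([max(c[1], 0.0) for c in cl], dtype=float)
        if weights.sum() <= 0:
            weights = np.ones_like(weights)
        locus = int(round(np.average(summits, weights=weights))) % L
        per_sample = {s: 0.0 for s in all_samples}
        present = {c: False for c in conditions}
        for _, w, sample, cond in cl:
            per_sample[sample] = max(per_sample[sample], w)
            present[cond] = True
        support = sum(1 for s in all_samples if any(
            e[2] == s for e in cl))
        targets.append(ConsolidatedTarget(
            locus=locus, support=support, per_sample_intensity=per_sample,
            condition_presence=present))
    targets.sort(key=lambda t: t.locus)
    return targets


# ---------------------------------------------------------------------------
# replicate reproducibility
# ---------------------------------------------------------------------------

def pearson_matrix(peaksets: Sequence[PeakSet],
                   merge_distance: float | None = None):
    """Pearson correlation of peak intensities among all samples.

    Targets define the union loci; each sample becomes a vector of
    intensities over them (0 where no peak was called). Samples with a
    zero-variance vector get NaN off-diagonal entries rather than raising.
    Returns a pandas DataFrame indexed by sample label.
    """
    if len(peaksets) < 2:
        raise ValueError("need at least 2 peak sets")
    targets = merge_replicates(peaksets, merge_distance)
    samples = [ps.sample for ps in peaksets]
    mat = np.array([[t.per_sample_intensity.get(s, 0.0) for t in targets]
                    for s in samples])
    n = len(samples)
    out = np.full((n, n), np.nan)
    sd = mat.std(axis=1) if targets else np.zeros(n)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            if sd[i] > 0 and sd[j] > 0:
                out[i, j] = out[j, i] = float(
                    stats.pearsonr(mat[i], mat[j]).statistic)
    return pd.DataFrame(out, index=samples, columns=samples)


# ---------------------------------------------------------------------------
# regulon comparison
# ---------------------------------------------------------------------------

def compare_regulons(targets_a: Sequence[ConsolidatedTarget],
                     targets_b: Sequence[ConsolidatedTarget],
                     mode: str = "by_gene", distance: float = 100.0,
                     genome_length: int | None = None):
    """Partition two regulons into (shared, only_a, only_b).

    ``by_gene``: shared means identical assigned gene id. ``by_locus``:
    shared means circular distance <= ``distance`` (greedy nearest-pair
    matching). The three parts are disjoint and jointly cover both inputs:
    shared is a list of (a, b) pairs.
    """
    if mode == "by_gene":
        if any(t.gene_id is None for t in list(targets_a) + list(targets_b)):
            raise ValueError("by_gene comparison requires annotated targets")
        b_by_gene = {}
        for t in targets_b:
            b_by_gene.setdefault(t.gene_id, []).append(t)
        shared, only_a = [], []
        used = set()
        for t in targets_a:
            cands = [u for u in b_by_gene.get(t.gene_id, ())
                     if id(u) not in used]
            if cands:
                shared.append((t, cands[0]))
                used.add(id(cands[0]))
            else:
                only_a.append(t)
        only_b = [t for t in targets_b if id(t) not in used]
        return shared, only_a, only_b
    if mode == "by_locus":
        if genome_length is None:
            raise ValueError("by_locus comparison needs genome_length")
        pairs = []
        for i, a in enumerate(targets_a):
            for j, b in enumerate(targets_b):
                d = circular_distance(a.locus, b.locus, genome_length)
                if d <= distance:
                    pairs.append((d, i, j))
        pairs.sort()
        used_a, used_b, shared = set(), set(), []
        for d, i, j in pairs:
            if i not in used_a and j not in used_b:
                shared.append((targets_a[i], targets_b[j]))
                used_a.add(i)
                used_b.add(j)
        only_a = [t for i, t in enumerate(targets_a) if i not in used_a]
        only_b = [t for j, t in enumerate(targets_b) if j not in used_b]
        return shared, only_a, only_b
    raise ValueError(f"unknown mode {mode!r}")


def condition_specific_sets(targets: Sequence[ConsolidatedTarget],
                            conditions: Sequence[str]) -> dict:
    """Partition targets by their condition-presence pattern.

    Keys: "all" when present in every condition, otherwise
    "only_<c1>[+<c2>...]" for the sorted set of present conditions.
    """
    out: dict = {}
    allset = frozenset(conditions)
    for t in targets:
        present = t.conditions_present() & allset
        if not present:
            key = "none"
        elif present == allset:
            key = "all"
        else:
            key = "only_" + "+".join(sorted(present))
        out.setdefault(key, []).append(t)
    return out


# ---------------------------------------------------------------------------
# correlation with expression
# ---------------------------------------------------------------------------

def _permutation_pvalue(x: np.ndarray, y: np.ndarray, method: str,
                        n_perm: int = 10_000, seed: int = 0):
    """Two-sided permutation p-value for Pearson/Spearman correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return float("nan"), float("nan")
    obs = float(xc @ yc / denom)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(yc, (n_perm, 1)), axis=1)
    r = perms @ xc / denom
    p = (1 + int(np.sum(np.abs(r) >= abs(obs) - 1e-12))) / (1 + n_perm)
    return obs, float(p)


def intensity_expression_correlation(targets: Sequence[ConsolidatedTarget],
                                     expr: pd.DataFrame,
                                     method: str = "spearman",
                                     n_perm: int = 10_000, seed: int = 0):
    """Correlate binding strength with expression-change magnitude.

    Pairs each annotated target's maximum per-sample intensity with the
    absolute log2 expression ratio of its assigned gene; unmatched genes
    are dropped. Returns (coefficient, permutation p-value, paired table).
    """
    lut = dict(zip(expr["gene_id"], expr["log2_ratio"]))
    rows = [(t.gene_id, t.max_intensity(), abs(lut[t.gene_id]))
            for t in targets if t.gene_id is not None and t.gene_id in lut]
    if len(rows) < 3:
        raise ValueError(f"need >= 3 matched target/gene pairs, got "
                         f"{len(rows)}")
    table = pd.DataFrame(rows, columns=["gene_id", "intensity",
                                        "abs_log2_ratio"])
    coef, p = _permutation_pvalue(table["intensity"].to_numpy(),
                                  table["abs_log2_ratio"].to_numpy(),
                                  method, n_perm, seed)
    return coef, p, table


def ddct_fold_change(ct_target_test: float, ct_ref_test: float,
                     ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative qPCR quantification: 2 ** -ddCt with
    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,ctrl - Ct_ref,ctrl).
    """
    for v in (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** -ddct)


# ---------------------------------------------------------------------------
# target table I/O
# ---------------------------------------------------------------------------

def targets_to_frame(targets: Sequence[ConsolidatedTarget]) -> pd.DataFrame:
    rows = []
    for t in targets:
        row = {"regulator": t.regulator, "locus": t.locus,
               "support": t.support, "gene_id": t.gene_id,
               "distance_to_tss": t.distance_to_tss,
               "location_class": t.location_class}
        for s, v in t.per_sample_intensity.items():
            row[f"intensity_{s}"] = v
        for c, v in t.condition_presence.items():
            row[f"in_{c}"] = int(v)
        rows.append(row)
    return pd.DataFrame(rows)


def write_targets(targets: Sequence[ConsolidatedTarget], path) -> None:
    targets_to_frame(targets).to_csv(path, sep="\t", index=False)


def read_targets(path) -> list:
    df = pd.read_csv(path, sep="\t")
    out = []
    int_cols = [c for c in df.columns if c.startswith("intensity_")]
    cond_cols = [c for c in df.columns if c.startswith("in_")]
    for _, r in df.iterrows():
        gid = r.get("gene_id")
        out.append(ConsolidatedTarget(
            locus=int(r["locus"]), support=int(r["support"]),
            per_sample_intensity={c[len("intensity_"):]: float(r[c])
                                  for c in int_cols},
            condition_presence={c[3:]: bool(r[c]) for c in cond_cols},
            gene_id=None if pd.isna(gid) else str(gid),
            distance_to_tss=None if pd.isna(r.get("distance_to_tss"))
            else int(r["distance_to_tss"]),
            location_class=None if pd.isna(r.get("location_class"))
            else str(r["location_class"]),
            regulator=str(r.get("regulator", "")) if
            not pd.isna(r.get("regulator")) else ""))
    return out
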