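"""UMI grouping and consensus error correction.

Reads are partitioned into molecule groups by single-linkage clustering of
their observed UMI sequences under a Levenshtein distance radius, within
pregroups that bound the quadratic pairwise search.  A group is then
collapsed either to a consensus sequence (star multiple alignment of up to
50 members, per-column majority vote) or to a single randomly chosen
representative (deduplication).  With simulated truth available, groups
are scored for purity: a group is pure iff all members carry the same true
UMI, i.e. descend from one molecule.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "UmiGroup",
    "GroupTruthAssessment",
    "levenshtein",
    "pairwise_distances",
    "pairwise_distance_distribution",
    "pregroup",
    "group_umis",
    "group_umis_multi",
    "consensus",
    "deduplicate",
    "assess_groups",
]


@dataclass
class UmiGroup:
    group_id: str
    member_indices: list[int]
    observed_umis: list[str]
    pregroup_id: str
    representative: str | None = None  # consensus sequence or member read id

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass(frozen=True)
class GroupTruthAssessment:
    group_id: str
    size: int
    true_umis_present: int

    @property
    def is_pure(self) -> bool:
        return self.true_umis_present == 1


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def pairwise_distances(umis: list[str], k: int | None = None) -> np.ndarray:
    """Condensed pairwise Levenshtein distance matrix (scipy pdist order).

    With a cap k, distances > k are stored as k + 1 (edlib early-abandon);
    only thresholds <= k may be applied downstream.
    """
    n = len(umis)
    out = np.empty(n * (n - 1) // 2, dtype=np.int32)
    cap = -1 if k is None else k
    pos = 0
    for i in range(n - 1):
        a = umis[i]
        for j in range(i + 1, n):
            if a == umis[j]:
                d = 0
            else:
                d = edlib.align(a, umis[j], mode="NW", task="distance", k=cap)[
                    "editDistance"
                ]
                if d == -1:
                    d = cap + 1
            out[pos] = d
            pos += 1
    return out


def pairwise_distance_distribution(
    umis: list[str], max_pairs: int | None = None, rng=None
) -> Counter:
    """Histogram of Levenshtein distances over all (or a sampled) UMI pairs."""
    n = len(umis)
    if n < 2:
        raise ValueError("need at least 2 UMIs")
    n_pairs = n * (n - 1) // 2
    hist: Counter = Counter()
    if max_pairs is None or n_pairs <= max_pairs:
        for i in range(n - 1):
            for j in range(i + 1, n):
                hist[levenshtein(umis[i], umis[j])] += 1
    else:
        rng = np.random.default_rng(rng)
        flat = rng.choice(n_pairs, size=max_pairs, replace=False)
        # invert condensed index -> (i, j)
        for f in flat:
            i = int(n - 2 - np.floor(np.sqrt(-8 * f + 4 * n * (n - 1) - 7) / 2 - 0.5))
            j = int(f + i + 1 - n * (n - 1) // 2 + (n - i) * (n - i - 1) // 2)
            hist[levenshtein(umis[i], umis[j])] += 1
    return hist


def pregroup(
    n_reads: int,
    mode: str = "none",
    true_umis: list[str] | None = None,
    block_size: int = 100,
    alignment_targets: list[str | None] | None = None,
) -> list[str]:
    """Pregroup label per read.

    by_true_umi_blocks: unique true UMIs are assigned, in order of first
    appearance, to blocks of `block_size`; reads follow their UMI's block.
    by_alignment_target: reads sharing a best-alignment target share a
    pregroup; unmapped reads (None) pool into one pregroup.
    none: a single universal pregroup.
    """
    if mode == "none":
        return ["pg0"] * n_reads
    if mode == "by_true_umi_blocks":
        if true_umis is None:
            raise ValueError("by_true_umi_blocks requires true UMIs")
        block_of: dict[str, int] = {}
        for u in true_umis:
            if u not in block_of:
                block_of[u] = len(block_of) // block_size
        return [f"pg{block_of[u]}" for u in true_umis]
    if mode == "by_alignment_target":
        if alignment_targets is None:
            raise ValueError("by_alignment_target requires targets")
        return [
            "pg_unmapped" if t is None else f"pg_{t}" for t in alignment_targets
        ]
    raise ValueError(f"unknown pregroup mode {mode!r}")


def group_umis(
    observed_umis: list[str],
    threshold: int,
    pregroups: list[str] | None = None,
    distance_cap: int | None = None,
) -> list[UmiGroup]:
    """Single-linkage UMI clustering within pregroups.

    Groups are the connected components of the graph joining reads whose
    observed UMIs are within `threshold` edits.  Duplicate UMI strings are
    collapsed before the quadratic distance pass.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if pregroups is None:
        pregroups = ["pg0"] * len(observed_umis)
    if len(pregroups) != len(observed_umis):
        raise ValueError("pregroups and observed_umis length mismatch")

    by_pg: dict[str, list[int]] = defaultdict(list)
    for idx, pg in enumerate(pregroups):
        by_pg[pg].append(idx)

    groups: list[UmiGroup] = []
    for pg in sorted(by_pg):
        indices = by_pg[pg]
        uniq: dict[str, list[int]] = defaultdict(list)
        for idx in indices:
            uniq[observed_umis[idx]].append(idx)
        seqs = list(uniq)
        comp = _connected_components(seqs, threshold, distance_cap)
        for members in comp:
            read_idx = sorted(i for s in members for i in uniq[seqs[s]])
            groups.append(
                UmiGroup(
                    group_id=f"g{len(groups)}",
                    member_indices=read_idx,
                    observed_umis=[observed_umis[i] for i in read_idx],
                    pregroup_id=pg,
                )
            )
    return groups


def _connected_components(
    seqs: list[str], threshold: int, distance_cap: int | None
) -> list[list[int]]:
    n = len(seqs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cap = threshold if distance_cap is None else distance_cap
    for i in range(n - 1):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            d = edlib.align(seqs[i], seqs[j], mode="NW", task="distance", k=cap)[
                "editDistance"
            ]
            if d != -1 and d <= threshold:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        comps[find(i)].append(i)
    return list(comps.values())


def _components_from_condensed(
    n: int, dists: np.ndarray, threshold: int
) -> list[list[int]]:
    """Connected components from a condensed distance matrix (pdist order)."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edge_idx = np.nonzero(dists <= threshold)[0]
    if edge_idx.size:
        # invert condensed indices to (i, j) pairs, vectorised
        f = edge_idx.astype(np.int64)
        i = (n - 2 - np.floor(
            np.sqrt(-8 * f + 4 * n * (n - 1) - 7) / 2 - 0.5
        )).astype(np.int64)
        j = f + i + 1 - n * (n - 1) // 2 + (n - i) * (n - i - 1) // 2
        for a, b in zip(i.tolist(), j.tolist()):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    comps: dict[int, list[int]] = defaultdict(list)
    for x in range(n):
        comps[find(x)].append(x)
    return list(comps.values())


def group_umis_multi(
    observed_umis: list[str],
    thresholds: list[int],
    pregroups: list[str] | None = None,
) -> dict[int, list[UmiGroup]]:
    """Group at several thresholds, computing pairwise distances once.

    Equivalent to calling group_umis per threshold but shares the
    quadratic Levenshtein pass (capped at max(thresholds)) across them.
    """
    if pregroups is None:
        pregroups = ["pg0"] * len(observed_umis)
    cap = max(thresholds)
    by_pg: dict[str, list[int]] = defaultdict(list)
    for idx, pg in enumerate(pregroups):
        by_pg[pg].append(idx)

    out: dict[int, list[UmiGroup]] = {t: [] for t in thresholds}
    for pg in sorted(by_pg):
        indices = by_pg[pg]
        uniq: dict[str, list[int]] = defaultdict(list)
        for idx in indices:
            uniq[observed_umis[idx]].append(idx)
        seqs = list(uniq)
        dists = pairwise_distances(seqs, k=cap)
        for t in thresholds:
            for members in _components_from_condensed(len(seqs), dists, t):
                read_idx = sorted(i for s in members for i in uniq[seqs[s]])
                out[t].append(
                    UmiGroup(
                        group_id=f"g{len(out[t])}",
                        member_indices=read_idx,
                        observed_umis=[observed_umis[i] for i in read_idx],
                        pregroup_id=pg,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Consensus calling


def _star_alignment_columns(medoid: str, others: list[str]) -> list[Counter]:
    """Column base counts of a star alignment of `others` onto the medoid.

    Columns are medoid positions plus insertion columns between them;
    reads aligned to the medoid with a global extended-CIGAR alignment.
    """
    m = len(medoid)
    # match/mismatch/deletion counts per medoid position; insertions keyed
    # by (medoid position before which they occur, offset within the run)
    cols: list[Counter] = [Counter() for _ in range(m)]
    ins_cols: dict[tuple[int, int], Counter] = {}
    n_reads = len(others) + 1
    for i, base in enumerate(medoid):
        cols[i][base] += 1
    for seq in others:
        res = edlib.align(seq, medoid, mode="NW", task="path")
        qpos = tpos = 0
        for length, op in _iter_cigar(res["cigar"]):
            if op in "=X":
                for k in range(length):
                    cols[tpos + k][seq[qpos + k]] += 1
                qpos += length
                tpos += length
            elif op == "D":  # medoid base absent from this read
                for k in range(length):
                    cols[tpos + k]["-"] += 1
                tpos += length
            elif op == "I":  # read bases absent from medoid
                for k in range(length):
                    key = (tpos, k)
                    ins_cols.setdefault(key, Counter())[seq[qpos + k]] += 1
                qpos += length
    # pad gap counts: reads not voting in a column implicitly vote gap
    ordered: list[tuple[tuple[int, int, int], Counter]] = []
    for i, c in enumerate(cols):
        c["-"] += n_reads - sum(c.values())
        ordered.append(((i, 1, 0), c))
    for (tpos, k), c in ins_cols.items():
        c["-"] += n_reads - sum(c.values())
        ordered.append(((tpos, 0, k), c))
    ordered.sort(key=lambda x: x[0])
    return [c for _, c in ordered]


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _majority_base(counts: Counter) -> str:
    """Majority vote; ties broken base-over-gap then alphabetically."""
    best = max(counts.values())
    winners = sorted(b for b, c in counts.items() if c == best)
    bases = [w for w in winners if w != "-"]
    return bases[0] if bases else "-"


def consensus(
    sequences: list[str], max_reads: int = 50, rng=None
) -> str:
    """Majority consensus from a star alignment anchored at the medoid.

    Groups larger than max_reads are subsampled uniformly at random under
    the run seed.  Per column the majority base wins; gap-majority columns
    are omitted.
    """
    if not sequences:
        raise ValueError("group is empty")
    seqs = list(sequences)
    if len(seqs) > max_reads:
        rng = np.random.default_rng(rng)
        idx = rng.choice(len(seqs), size=max_reads, replace=False)
        seqs = [seqs[i] for i in sorted(idx)]
    if len(seqs) == 1:
        return seqs[0]
    medoid_idx = _medoid(seqs)
    medoid = seqs[medoid_idx]
    others = [s for i, s in enumerate(seqs) if i != medoid_idx]
    cols = _star_alignment_columns(medoid, others)
    return "".join(
        b for b in (_majority_base(c) for c in cols) if b != "-"
    )


def _medoid(seqs: list[str]) -> int:
    """Index of the member minimising summed edit distance to the rest."""
    n = len(seqs)
    totals = np.zeros(n)
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = levenshtein(seqs[i], seqs[j])
            totals[i] += d
            totals[j] += d
    return int(np.argmin(totals))


def deduplicate(member_ids: list, rng=None):
    """Uniformly random representative of a group (seed-deterministic)."""
    if not member_ids:
        raise ValueError("group is empty")
    rng = np.random.default_rng(rng)
    return member_ids[int(rng.integers(0, len(member_ids)))]


def assess_groups(
    groups: list[UmiGroup], true_umi_per_read: list[str]
) -> tuple[list[GroupTruthAssessment], dict]:
    """Purity and size of each group against simulation truth.

    Returns per-group assessments and a summary with the fraction of pure
    groups and the group-size histogram.
    """
    assessments = []
    for g in groups:
        try:
            truths = {true_umi_per_read[i] for i in g.member_indices}
        except IndexError as exc:
            raise ValueError("truth missing for a group member") from exc
        assessments.append(GroupTruthAssessment(g.group_id, g.size, len(truths)))
    n = len(assessments)
    summary = {
        "n_groups": n,
        "fraction_pure": (sum(a.is_pure for a in assessments) / n) if n else float("nan"),
        "size_histogram": dict(Counter(a.size for a in assessments)),
    }
    return assessments, summary
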