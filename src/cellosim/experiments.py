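"""End-to-end simulation studies.

Two orchestrated experiments:

* the repeat-mapping experiment — simulate UMI-tagged long reads from a
  planted repeat family under several arms (perfect identity, naive
  nanopore-identity mapping, UMI consensus correction, UMI deduplication,
  optionally with perfect grouping from truth UMIs), map every arm's
  output back, and tabulate read classes, group sizes, per-element
  specificity and post-processing identity;

* the UMI-design sweep — UMI-only reads over a factorial grid of UMI
  length, pattern, identity model, coverage and Levenshtein grouping
  threshold, scoring group purity and group counts against truth.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from . import mapping as mp
from . import preprocess as pp
from . import readsim as rs
from . import umi as um
from .reference import RepeatAnnotation, RepeatFamilySpec, plant_copies

__all__ = [
    "ArmSpec",
    "SweepSpec",
    "default_fixture",
    "run_mapping_experiment",
    "run_umi_sweep",
    "minimum_adequate_umi_length",
    "report",
]

ARM_NAMES = ("perfect", "ont_naive", "sarlacc_corrected", "sarlacc_dedup")

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class ArmSpec:
    name: str  # one of ARM_NAMES
    coverage: int = 1
    grouping: str = "none"  # none | levenshtein | perfect_grouping
    threshold: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ARM_NAMES:
            raise ValueError(f"unknown arm {self.name!r}")
        if self.grouping == "none" and self.name not in ("perfect", "ont_naive"):
            raise ValueError("grouping=none only valid for naive arms")
        if self.name in ("sarlacc_corrected", "sarlacc_dedup") and self.grouping == "none":
            raise ValueError("processed arms need a grouping mode")

    @property
    def label(self) -> str:
        pg = "_pg" if self.grouping == "perfect_grouping" else ""
        return f"{self.name}_{self.coverage}x{pg}"


@dataclass(frozen=True)
class SweepSpec:
    n_umis: int = 10_000
    lengths: tuple[int, ...] = (10, 20, 30, 40, 50)
    patterns: tuple[str, ...] = ("RYN",)
    coverages: tuple[int, ...] = (5,)
    identities: tuple[str, ...] = ("ont",)
    thresholds: tuple[int, ...] = (2, 6, 10, 14)
    pregroup: tuple[str, ...] = ("blocks_of_100",)
    block_size: int = 100
    error_model: rs.ErrorModelParams = field(default_factory=rs.ErrorModelParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lengths", "patterns", "coverages", "identities", "thresholds", "pregroup"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")


def default_fixture(seed: int = 0) -> tuple[dict[str, str], list[RepeatAnnotation]]:
    """Desk-scale repeat family spanning young-to-old similarity regimes.

    30 copies of a 3 kb ancestor in a 300 kb genome, copies cycling a
    divergence grid of {5, 20, 80, 200} milliDivergence.
    """
    spec = RepeatFamilySpec(
        ancestral_length=3000,
        copy_number=30,
        genome_length=300_000,
        divergence_grid=(5.0, 20.0, 80.0, 200.0),
        seed=seed,
    )
    return plant_copies(spec)


# ---------------------------------------------------------------------------
# Mapping experiment


def _truth_from_molecules(molecules) -> dict[str, dict]:
    return {
        m.molecule_id: {
            "element_id": m.element_id,
            "chrom": m.chrom,
            "start": m.start,
            "end": m.end,
            "cdna": m.cdna,
        }
        for m in molecules
    }


def _seq_identity(a: str, b: str) -> float:
    """Global alignment identity between two sequences."""
    cigar = edlib.align(a, b, mode="NW", task="path")["cigar"]
    return mp.read_identity(cigar)


def _naive_arm(molecules, arm, config, genome, annotations, rng):
    reads = rs.emit_reads(molecules, config, np.random.default_rng(arm.seed))
    alignments, truth = {}, {}
    for r in reads:
        meta = rs.parse_read_name(r.read_id)
        truth[r.read_id] = {
            "element_id": meta["element_id"],
            "chrom": meta["chrom"],
            "start": meta["start"],
            "end": meta["end"],
        }
        aln = mp.oracle_map(r.sequence, genome, rng, read_id=r.read_id)
        alignments[r.read_id] = aln
    classes = mp.classify(alignments, truth, annotations=annotations)
    identities = [
        float(r.drawn_identity) for r in reads if not np.isnan(r.drawn_identity)
    ]
    group_sizes = {c.read_id: 1 for c in classes}
    return reads, alignments, truth, classes, identities, group_sizes, 0


def _processed_arm(molecules, arm, config, genome, annotations, rng):
    reads = rs.emit_reads(molecules, config, np.random.default_rng(arm.seed))
    adapter_cfg = pp.AdapterConfig(
        tso_sequence=config.adapter_layout.tso,
        dt_adapter_sequence=config.adapter_layout.dt_adapter,
        barcode_whitelist=(config.barcode,),
        umi_length=config.umi_length,
        barcode_length=len(config.barcode),
    )
    kept, excluded = pp.preprocess_reads(reads, adapter_cfg)
    truth_by_read = {r.read_id: rs.parse_read_name(r.read_id) for r in reads}
    mol_truth = _truth_from_molecules(molecules)

    observed = [r.umi for r in kept]
    if arm.grouping == "perfect_grouping":
        by_true: dict[str, list[int]] = defaultdict(list)
        for i, r in enumerate(kept):
            by_true[truth_by_read[r.read_id]["true_umi"]].append(i)
        groups = [
            um.UmiGroup(f"g{k}", idx, [observed[i] for i in idx], "pg0")
            for k, idx in enumerate(by_true.values())
        ]
    else:
        groups = um.group_umis(observed, arm.threshold)

    grp_rng = np.random.default_rng(arm.seed + 1)
    alignments, truth, unresolved = {}, {}, set()
    identities = []
    unit_group_size = {}
    for g in groups:
        members = [kept[i] for i in g.member_indices]
        true_umis = {truth_by_read[m.read_id]["true_umi"] for m in members}
        mol_counts = Counter(
            truth_by_read[m.read_id]["molecule_id"] for m in members
        )
        # attribute the unit to the plurality molecule (ties: lexicographic)
        top = max(sorted(mol_counts), key=lambda k: mol_counts[k])
        unit_id = f"unit_{arm.label}_{g.group_id}"
        t = mol_truth[top]
        truth[unit_id] = {k: t[k] for k in ("element_id", "chrom", "start", "end")}
        unit_group_size[unit_id] = g.size
        if len(true_umis) > 1:
            unresolved.add(unit_id)
            alignments[unit_id] = None
            continue
        if arm.name == "sarlacc_corrected":
            seq = um.consensus([m.cdna for m in members], rng=grp_rng)
        else:
            seq = um.deduplicate([m.cdna for m in members], rng=grp_rng)
        identities.append(_seq_identity(seq, t["cdna"]))
        alignments[unit_id] = mp.oracle_map(seq, genome, rng, read_id=unit_id)
    classes = mp.classify(alignments, truth, unresolved, annotations=annotations)
    sizes = {c.read_id: unit_group_size[c.read_id] for c in classes}
    return reads, alignments, truth, classes, identities, sizes, len(excluded)


def run_mapping_experiment(
    genome: dict[str, str],
    annotations: list[RepeatAnnotation],
    arms: list[ArmSpec],
    base_config: rs.SimulationConfig | None = None,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Run experiment arms over one shared molecule truth.

    All arms share the same molecules (windows and true UMIs); each arm
    re-emits its reads at its own coverage with errors drawn under the
    arm's seed.  Returns tidy tables: per-arm class counts, group-size by
    class, per-element specificity, and post-processing identity moments.
    """
    base_config = base_config or rs.SimulationConfig()
    rng = np.random.default_rng(seed)
    molecules = rs.simulate_molecules(
        annotations, genome, base_config, np.random.default_rng(base_config.seed)
    )

    class_rows, size_rows, spec_rows, ident_rows = [], [], [], []
    for arm in arms:
        config = rs.SimulationConfig(
            window_length=base_config.window_length,
            stride=base_config.stride,
            coverage=arm.coverage,
            identity_mode="perfect" if arm.name == "perfect" else "ont",
            umi_length=base_config.umi_length,
            umi_pattern=base_config.umi_pattern,
            barcode=base_config.barcode,
            adapter_layout=base_config.adapter_layout,
            error_model=base_config.error_model,
            seed=arm.seed,
        )
        runner = _naive_arm if arm.grouping == "none" else _processed_arm
        reads, alignments, truth, classes, identities, sizes, n_excl = runner(
            molecules, arm, config, genome, annotations, rng
        )
        counts = Counter(c.klass for c in classes)
        class_rows.append(
            {
                "arm": arm.label,
                "coverage": arm.coverage,
                "n_reads_simulated": len(reads),
                "n_units": len(classes),
                "n_qc_dropped": n_excl,
                "mapped": counts.get("mapped", 0),
                "mismapped": counts.get("mismapped", 0),
                "unmapped": counts.get("unmapped", 0),
                "unresolved": counts.get("unresolved", 0),
                "n_molecules_true": len(molecules),
                "mean_identity_vs_truth": float(np.mean(identities))
                if identities
                else float("nan"),
            }
        )
        size_counter = Counter((c.klass, sizes[c.read_id]) for c in classes)
        for (klass, size), n in sorted(size_counter.items()):
            size_rows.append(
                {"arm": arm.label, "class": klass, "group_size": size, "count": n}
            )
        summaries = mp.element_summary(classes, alignments, annotations)
        for el_id in sorted(summaries):
            s = summaries[el_id]
            spec_rows.append(
                {
                    "arm": arm.label,
                    "element_id": el_id,
                    "n_mapped": s.n_mapped,
                    "n_mismapped_own": s.n_mismapped_own,
                    "n_unmapped": s.n_unmapped,
                    "n_unresolved": s.n_unresolved,
                    "n_mismapped_in": s.n_mismapped_in,
                    "fraction_mapped": s.fraction_mapped,
                    "specificity": s.specificity,
                }
            )
        ident_rows.append(
            {
                "arm": arm.label,
                "coverage": arm.coverage,
                "n": len(identities),
                "mean_identity": float(np.mean(identities))
                if identities
                else float("nan"),
                "median_identity": float(np.median(identities))
                if identities
                else float("nan"),
            }
        )
    return {
        "classes": pd.DataFrame(class_rows),
        "group_sizes": pd.DataFrame(size_rows),
        "element_summary": pd.DataFrame(spec_rows),
        "identity": pd.DataFrame(ident_rows),
    }


# ---------------------------------------------------------------------------
# UMI-design sweep


def _draw_umis(n: int, length: int, pattern: str, rng) -> list[str]:
    """n independent UMI draws; collisions are kept (short UMIs collide)."""
    return [rs.make_umi(length, pattern, rng) for _ in range(n)]


def run_umi_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Factorial UMI-design sweep; one row per grid cell.

    Each of the n_umis draws is one molecule, read `coverage` times; ONT
    cells corrupt every read with a freshly drawn identity.  UMIs are
    drawn with replacement, so at short lengths distinct molecules can
    share a UMI string — an intrinsic failure mode of short UMIs.
    Grouping is scored against truth: the fraction of pure groups (one
    distinct true UMI sequence per group) and the group count against the
    number of distinct true UMIs.  Pairwise-distance histograms of the
    true UMIs ride along in a JSON-encoded companion column.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for length in spec.lengths:
        for pattern in spec.patterns:
            true_umis = _draw_umis(spec.n_umis, length, pattern, rng)
            n_distinct = len(set(true_umis))
            dist_hist = um.pairwise_distance_distribution(
                true_umis, max_pairs=50_000, rng=rng
            )
            dist_json = json.dumps(dict(sorted(dist_hist.items())))
            for identity_mode in spec.identities:
                for coverage in spec.coverages:
                    reads, read_truth = [], []
                    for u in true_umis:
                        for _ in range(coverage):
                            if identity_mode == "perfect":
                                reads.append(u)
                            else:
                                ident = float(rs.draw_identity(spec.error_model, rng))
                                reads.append(
                                    rs.corrupt(u, ident, spec.error_model.error_mix, rng)
                                )
                            read_truth.append(u)
                    for pg_mode in spec.pregroup:
                        if pg_mode == "none":
                            labels = um.pregroup(len(reads), "none")
                        elif pg_mode == "blocks_of_100":
                            labels = um.pregroup(
                                len(reads),
                                "by_true_umi_blocks",
                                true_umis=read_truth,
                                block_size=spec.block_size,
                            )
                        else:
                            raise ValueError(f"unknown pregroup mode {pg_mode!r}")
                        grouped = um.group_umis_multi(
                            reads, list(spec.thresholds), labels
                        )
                        for threshold in spec.thresholds:
                            groups = grouped[threshold]
                            _, summary = um.assess_groups(groups, read_truth)
                            sizes = summary["size_histogram"]
                            rows.append(
                                {
                                    "umi_length": length,
                                    "pattern": pattern,
                                    "identity": identity_mode,
                                    "coverage": coverage,
                                    "threshold": threshold,
                                    "pregroup": pg_mode,
                                    "n_molecules": n_distinct,
                                    "n_reads": len(reads),
                                    "n_groups": summary["n_groups"],
                                    "fraction_pure": summary["fraction_pure"],
                                    "mean_group_size": len(reads)
                                    / summary["n_groups"],
                                    "size_histogram": json.dumps(
                                        dict(sorted(sizes.items()))
                                    ),
                                    "distance_histogram": dist_json,
                                }
                            )
    return pd.DataFrame(rows)


def minimum_adequate_umi_length(
    sweep: pd.DataFrame,
    purity_min: float = 0.95,
    count_tol: float = 0.05,
) -> int | None:
    """Smallest UMI length whose best threshold groups reads correctly.

    A length passes when, at some threshold, the fraction of pure groups
    is >= purity_min and the group count is within count_tol of the true
    molecule count.  Returns None if no length in the sweep passes.
    """
    for length in sorted(sweep["umi_length"].unique()):
        sub = sweep[sweep["umi_length"] == length]
        ok = (sub["fraction_pure"] >= purity_min) & (
            (sub["n_groups"] - sub["n_molecules"]).abs()
            <= count_tol * sub["n_molecules"]
        )
        if ok.any():
            return int(length)
    return None


def report(tables: dict[str, pd.DataFrame], out_prefix) -> dict:
    """Write each table as TSV plus one JSON index; returns the index."""
    import os

    index = {"schema_version": SCHEMA_VERSION, "tables": {}}
    out_prefix = str(out_prefix)
    os.makedirs(os.path.dirname(out_prefix) or ".", exist_ok=True)
    for name, df in tables.items():
        if not isinstance(df, pd.DataFrame):
            raise ValueError(f"table {name!r} is not a DataFrame")
        path = f"{out_prefix}.{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        index["tables"][name] = {"path": path, "n_rows": int(len(df))}
    with open(f"{out_prefix}.index.json", "w") as fh:
        json.dump(index, fh, indent=2)
    return index
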