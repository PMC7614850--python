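"""Adapter scanning, full-length filtering, demultiplexing, UMI extraction."""

import edlib
import numpy as np
import pytest

from cellosim import preprocess as pp
from cellosim import readsim as rs
from cellosim.reference import generate_ancestral, reverse_complement

CFG = pp.AdapterConfig()


def _mk_read(seq, read_id="r|m|e|c|0|1|+|U"):
    return rs.SimulatedRead(read_id, seq, "I" * len(seq), 1.0)


def _template(cdna, umi="A" * 22, barcode=rs.DEFAULT_BARCODE):
    return rs.DEFAULT_TSO + cdna + umi + barcode + rs.DEFAULT_DT_ADAPTER


class TestScanReadEnds:
    def test_perfect_forward_read(self):
        read = _mk_read(_template(generate_ancestral(1000, seed=1)))
        hits = pp.scan_read_ends(read, CFG)
        kinds = {(h.adapter, h.end, h.orientation) for h in hits}
        assert ("tso", "head", "+") in kinds
        assert ("dt", "tail", "+") in kinds

    def test_exact_hit_spans_full_adapter(self):
        read = _mk_read(_template(generate_ancestral(1000, seed=2)))
        hits = pp.scan_read_ends(read, CFG)
        tso = max((h for h in hits if h.adapter == "tso"), key=lambda h: h.score)
        assert (tso.start, tso.stop) == (0, len(rs.DEFAULT_TSO))
        dt = max((h for h in hits if h.adapter == "dt"), key=lambda h: h.score)
        assert (dt.start, dt.stop) == (
            len(read.sequence) - len(rs.DEFAULT_DT_ADAPTER),
            len(read.sequence),
        )

    def test_reverse_complement_read_detected(self):
        read = _mk_read(reverse_complement(_template(generate_ancestral(900, seed=3))))
        hits = pp.scan_read_ends(read, CFG)
        kinds = {(h.adapter, h.end, h.orientation) for h in hits}
        assert ("tso", "tail", "-") in kinds
        assert ("dt", "head", "-") in kinds

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            pp.scan_read_ends(_mk_read(""), CFG)


class TestFilterFullLength:
    def test_forward_read_kept_unchanged(self):
        seq = _template(generate_ancestral(800, seed=4))
        kept, discarded = pp.filter_full_length([_mk_read(seq)], CFG)
        assert len(kept) == 1 and not discarded
        assert kept[0].sequence == seq

    def test_reverse_read_reoriented_to_canonical(self):
        seq = _template(generate_ancestral(800, seed=5))
        kept, discarded = pp.filter_full_length([_mk_read(reverse_complement(seq))], CFG)
        assert len(kept) == 1 and not discarded
        assert kept[0].sequence == seq

    def test_adapterless_read_discarded(self):
        kept, discarded = pp.filter_full_length(
            [_mk_read(generate_ancestral(1000, seed=6))], CFG
        )
        assert not kept and discarded[0].reason in ("no_adapters", "missing_adapter_pair")

    def test_single_adapter_read_discarded(self):
        seq = rs.DEFAULT_TSO + generate_ancestral(1000, seed=7)
        kept, discarded = pp.filter_full_length([_mk_read(seq)], CFG)
        assert not kept and len(discarded) == 1

    def test_partition_is_conservative(self):
        reads = [
            _mk_read(_template(generate_ancestral(500, seed=s))) for s in range(3)
        ] + [_mk_read(generate_ancestral(700, seed=9))]
        kept, discarded = pp.filter_full_length(reads, CFG)
        assert len(kept) + len(discarded) == len(reads)


class TestInternalAdapterPolicy:
    def _chimera(self, seed):
        a = _template(generate_ancestral(700, seed=seed))
        b = _template(generate_ancestral(700, seed=seed + 100))
        return _mk_read(a + b, read_id=f"chim{seed}|m|e|c|0|1|+|U")

    def test_rare_chimeras_filtered(self):
        reads = [
            _mk_read(_template(generate_ancestral(700, seed=s)), read_id=f"ok{s}|m|e|c|0|1|+|U")
            for s in range(9)
        ] + [self._chimera(50)]
        decision, survived, dropped = pp.internal_adapter_policy(reads, CFG)
        assert decision == "filter"
        assert len(survived) == 9 and len(dropped) == 1
        assert dropped[0].reason == "internal_adapter"
        assert dropped[0].read_id.startswith("chim")

    def test_common_chimeras_split(self):
        reads = [self._chimera(s) for s in range(4)] + [
            _mk_read(_template(generate_ancestral(700, seed=s + 200)))
            for s in range(4)
        ]
        decision, survived, dropped = pp.internal_adapter_policy(reads, CFG)
        assert decision == "split"
        assert not dropped
        assert len(survived) == 12  # 4 chimeras -> 2 halves each, 4 intact
        halves = [r for r in survived if r.read_id.endswith(("/1", "/2"))]
        assert len(halves) == 8
        for h in halves:
            assert len(h.sequence) < 700 + 2 * len(_template(""))

    def test_clean_arm_untouched(self):
        reads = [_mk_read(_template(generate_ancestral(700, seed=s))) for s in range(5)]
        decision, survived, dropped = pp.internal_adapter_policy(reads, CFG)
        assert decision == "filter" and len(survived) == 5 and not dropped


class TestDemultiplex:
    def _annotated(self, barcode):
        seq = _template(generate_ancestral(600, seed=11), barcode=barcode)
        kept, _ = pp.filter_full_length([_mk_read(seq)], CFG)
        return kept[0]

    def test_exact_barcode_assigned(self):
        read = self._annotated(rs.DEFAULT_BARCODE)
        assert pp.demultiplex([read], CFG)[read.read_id] == rs.DEFAULT_BARCODE

    def test_three_errors_still_assigned(self):
        mutated = "T" + rs.DEFAULT_BARCODE[1:-2] + "CC"
        read = self._annotated(mutated)
        assert pp.demultiplex([read], CFG)[read.read_id] == rs.DEFAULT_BARCODE

    def test_distant_barcode_unassigned(self):
        read = self._annotated("G" * len(rs.DEFAULT_BARCODE))
        assert pp.demultiplex([read], CFG)[read.read_id] is None

    def test_tie_between_whitelist_entries_unassigned(self):
        bc_a = "AAAAAAAACCCCCCCC"
        bc_b = "AAAAAAAACCCCCCCG"  # distance 1 from bc_a
        cfg = pp.AdapterConfig(barcode_whitelist=(bc_a, bc_b))
        # observed barcode equidistant (1) from both entries
        read = self._annotated("AAAAAAAACCCCCCCT")
        assert pp.demultiplex([read], cfg)[read.read_id] is None


class TestExtractUmi:
    def test_round_trip_on_perfect_reads(self, perfect_reads):
        reads, truth, _ = perfect_reads
        kept, _ = pp.filter_full_length(reads, CFG)
        assert len(kept) == len(reads)
        umi_by_mol = dict(zip(truth.molecule_id, truth.umi))
        for read in kept:
            meta = rs.parse_read_name(read.read_id)
            umi, cdna = pp.extract_umi(read, CFG)
            assert umi == umi_by_mol[meta["molecule_id"]]
            assert len(cdna) == 2000

    def test_too_short_read_flagged(self):
        seq = _template("", umi="A" * 10)  # 12 nt short of the layout
        kept, _ = pp.filter_full_length([_mk_read(seq)], CFG)
        if kept:
            assert pp.extract_umi(kept[0], CFG) is None
            assert kept[0].reason == "too_short_for_layout"


class TestPreprocessReads:
    def test_conservation_and_reasons(self, ont_reads):
        reads, _, _ = ont_reads
        kept, excluded = pp.preprocess_reads(reads, CFG)
        assert len(kept) + len(excluded) == len(reads)
        assert all(r.reason for r in excluded)
        assert all(r.umi is not None and r.cdna is not None for r in kept)

    def test_majority_of_ont_reads_survive(self, ont_reads):
        reads, _, _ = ont_reads
        kept, _ = pp.preprocess_reads(reads, CFG)
        assert len(kept) >= 0.8 * len(reads)

    def test_extracted_umis_near_truth(self, ont_reads):
        reads, truth, _ = ont_reads
        kept, _ = pp.preprocess_reads(reads, CFG)
        umi_by_mol = dict(zip(truth.molecule_id, truth.umi))
        dists = []
        for read in kept:
            true_umi = umi_by_mol[rs.parse_read_name(read.read_id)["molecule_id"]]
            dists.append(
                edlib.align(read.umi, true_umi, mode="NW", task="distance")["editDistance"]
            )
        # at ~92% identity a 22-mer carries ~1.8 expected edits; positional
        # extraction adds drift, but the bulk must stay well below
        # the intra-molecule grouping threshold
        assert np.median(dists) <= 4
        assert np.mean(dists) <= 6

    def test_perfect_reads_all_survive(self, perfect_reads):
        reads, _, _ = perfect_reads
        kept, excluded = pp.preprocess_reads(reads, CFG)
        assert not excluded
        assert len(kept) == len(reads)
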