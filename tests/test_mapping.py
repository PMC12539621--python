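import numpy as np
import pytest

from spacerscan.core import CoordinateError, ReferenceSet, circular_window, revcomp
from spacerscan.mapping import (
    ProtospacerHit,
    SpacerMapper,
    classify_sources,
    extract_pam,
    map_spacer,
    pam_window,
)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestMapSpacer:
    def test_exact_plasmid_forward(self, small_refs):
        spacer = small_refs.plasmid[1000:1032]
        hit = map_spacer(spacer, small_refs)
        assert (hit.source, hit.start, hit.strand, hit.edit_distance) == \
            ("plasmid", 1000, "+", 0)

    def test_revcomp_chromosome_window(self, small_refs):
        window = small_refs.chromosome[5000:5033]
        hit = map_spacer(revcomp(window), small_refs)
        assert (hit.source, hit.start, hit.strand) == ("chromosome", 5000, "-")

    def test_random_spacers_unmapped(self, small_refs, rng):
        n_unmapped = sum(
            map_spacer(random_dna(rng, 33), small_refs, max_edits=2).source
            == "unmapped"
            for _ in range(20)
        )
        assert n_unmapped == 20

    def test_ambiguous_across_replicons(self, rng):
        shared = random_dna(rng, 32)
        chrom = random_dna(rng, 5000) + shared + random_dna(rng, 5000)
        plas = random_dna(rng, 500) + shared + random_dna(rng, 500)
        refs = ReferenceSet(chromosome=chrom, plasmid=plas)
        hit = map_spacer(shared, refs)
        assert hit.source == "ambiguous"
        assert hit.n_equal_best >= 2

    def test_multimapper_within_replicon_lowest_start(self, rng):
        dup = random_dna(rng, 32)
        chrom = random_dna(rng, 1000) + dup + random_dna(rng, 1000) + dup \
            + random_dna(rng, 1000)
        refs = ReferenceSet(chromosome=chrom, plasmid=random_dna(rng, 300))
        hit = map_spacer(dup, refs)
        assert hit.source == "chromosome"
        assert hit.start == 1000
        assert hit.n_equal_best == 2

    def test_mutated_spacer_mapped_with_edits(self, small_refs):
        spacer = list(small_refs.chromosome[2000:2032])
        spacer[10] = "A" if spacer[10] != "A" else "C"
        hit = map_spacer("".join(spacer), small_refs, max_edits=2)
        assert (hit.source, hit.start, hit.edit_distance) == ("chromosome", 2000, 1)

    def test_circular_wrap_match(self, rng):
        chrom = random_dna(rng, 4000)
        spacer = chrom[3990:] + chrom[:22]  # spans the origin
        refs = ReferenceSet(chromosome=chrom, plasmid=random_dna(rng, 400))
        hit = map_spacer(spacer, refs)
        assert (hit.source, hit.start, hit.strand) == ("chromosome", 3990, "+")

    def test_exact_path_equals_scan(self, small_refs, rng):
        mapper = SpacerMapper(small_refs)
        for _ in range(15):
            start = int(rng.integers(0, len(small_refs.chromosome) - 40))
            spacer = small_refs.chromosome[start:start + 32]
            exact = mapper._exact_hits(spacer)
            dist, scanned = mapper._scan_hits(spacer)
            assert dist == 0
            norm = lambda hits: sorted(
                (s, mapper._to_forward(s, st_, p, ln), st_)
                for s, st_, p, ln in hits)
            assert norm(exact) == norm(scanned)

    def test_truth_recovery_error_free(self, clean_simulation):
        cfg, refs, model, events, reads = clean_simulation
        mapper = SpacerMapper(refs)
        for e in events:
            hit = mapper.map(e.spacer)
            assert (hit.source, hit.start, hit.strand) == \
                (e.source, e.start, e.strand), e


class TestExtractPam:
    def test_constructed_aag(self, rng):
        proto = random_dna(rng, 32)
        chrom = random_dna(rng, 500) + "TTAAG" + proto[1:] + random_dna(rng, 500)
        # protospacer starts at the G of ...ttAAG...
        refs = ReferenceSet(chromosome=chrom, plasmid=random_dna(rng, 100))
        hit = ProtospacerHit(spacer="G" + proto[1:31], source="chromosome",
                             start=504, strand="+", length=31, edit_distance=0)
        assert extract_pam(hit, refs)[:3] == "AAG"

    def test_strand_symmetry(self, rng):
        # the same physical site read on the minus strand of its revcomp
        # yields the identical PAM string
        for _ in range(20):
            ref_fwd = random_dna(rng, 200)
            start, m = 80, 32
            pam_fwd = pam_window(ref_fwd, start, m, "+", circular=True)
            ref_rc = revcomp(ref_fwd)
            start_rc = len(ref_fwd) - (start + m)
            pam_rc = pam_window(ref_rc, start_rc, m, "-", circular=True)
            assert pam_fwd == pam_rc

    def test_wrap_at_origin(self, rng):
        plas = random_dna(rng, 300)
        chrom = random_dna(rng, 2000)
        refs = ReferenceSet(chromosome=chrom, plasmid=plas)
        hit = ProtospacerHit(spacer=plas[:32], source="plasmid", start=0,
                             strand="+", length=32, edit_distance=0)
        assert extract_pam(hit, refs) == plas[-2:] + plas[0]

    def test_unmapped_raises(self, small_refs):
        hit = ProtospacerHit(spacer="ACGT", source="unmapped")
        with pytest.raises(ValueError):
            extract_pam(hit, small_refs)

    def test_four_base_window_config(self, rng):
        ref = random_dna(rng, 100)
        pam = pam_window(ref, 50, 30, "+", circular=True, offset=-2, width=4)
        assert pam == ref[48:52]

    def test_planted_aag_recovered(self, model):
        import math
        from spacerscan.simulate import SimulationConfig, generate_references, plant_events
        cfg = SimulationConfig(seed=71, n_events=150, pam_bias=math.inf)
        rng = np.random.default_rng(cfg.seed)
        refs, model, _ = generate_references(cfg, rng)
        events = plant_events(refs, model, cfg, rng)
        mapper = SpacerMapper(refs)
        for e in events:
            hit = mapper.map(e.spacer)
            assert extract_pam(hit, refs) == "AAG"


class TestClassifySources:
    def _hit(self, source):
        return ProtospacerHit(spacer="A", source=source)

    def test_counts(self):
        hits = [self._hit("chromosome")] * 91 + [self._hit("plasmid")] * 9
        assert classify_sources(hits) == {
            "chromosome": 91, "plasmid": 9, "ambiguous": 0, "unmapped": 0}

    def test_empty(self):
        assert classify_sources([]) == {
            "chromosome": 0, "plasmid": 0, "ambiguous": 0, "unmapped": 0}

    def test_total_conserved(self, rng):
        cats = ["chromosome", "plasmid", "ambiguous", "unmapped"]
        hits = [self._hit(cats[i]) for i in rng.integers(0, 4, 57)]
        assert sum(classify_sources(hits).values()) == 57
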