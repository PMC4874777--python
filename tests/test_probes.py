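"""Targeting-region screens, index primers, template assembly, partitioning."""

import numpy as np
import pandas as pd
import pytest

from tauseq import probes


def random_transcripts(n, length, seed=0, gc=0.52):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return {
        f"t{i}": "".join(rng.choice(list("ACGT"), p=p, size=length))
        for i in range(n)
    }


def validate_tr(tr: probes.TargetingRegion, transcripts, all_trs,
                c=probes.TRConstraints()):
    """Independent validator of every targeting-region constraint."""
    assert len(tr.sequence) == c.length
    gc = 100.0 * sum(tr.sequence.count(b) for b in "GC") / c.length
    assert c.gc_range[0] <= gc <= c.gc_range[1]
    tm = probes.duplex_tm(tr.sequence, na_mM=c.na_mM, formamide_pct=c.formamide_pct)
    assert c.tm_range[0] <= tm <= c.tm_range[1]
    # the stored sequence is the reverse complement of the transcript window
    window = transcripts[tr.transcript_id][tr.start - 1 : tr.start - 1 + c.length]
    assert probes.revcomp(tr.sequence) == window
    # cross-hybridization: no shared >= k-mer with any other transcript
    k = c.crosshyb_k
    kmers = {window[i : i + k] for i in range(len(window) - k + 1)}
    rc = probes.revcomp(window)
    kmers |= {rc[i : i + k] for i in range(len(rc) - k + 1)}
    for tid, seq in transcripts.items():
        if tid == tr.transcript_id:
            continue
        both = seq + "|" + probes.revcomp(seq)
        assert not any(km in both for km in kmers)
    # non-overlap with other accepted TRs on the same transcript
    for other in all_trs:
        if other is tr or other.transcript_id != tr.transcript_id:
            continue
        assert (tr.start + c.length <= other.start
                or other.start + c.length <= tr.start)


def validate_primer(p: probes.IndexPrimer, screened,
                    c=probes.PrimerConstraints()):
    s = p.sequence
    assert len(s) == c.length
    gc = 100.0 * sum(s.count(b) for b in "GC") / len(s)
    assert c.gc_range[0] <= gc <= c.gc_range[1]
    assert c.tm_range[0] <= probes.primer_tm(s, na_mM=c.na_mM) <= c.tm_range[1]
    for b in "ACGT":
        assert b * (c.max_run + 1) not in s
    clamp = sum(s[-5:].count(b) for b in "GC")
    assert c.clamp_gc[0] <= clamp <= c.clamp_gc[1]
    k = c.homology_k
    for other in screened:
        hay = other.upper() + "|" + probes.revcomp(other.upper())
        for cand in (s, probes.revcomp(s)):
            assert not any(
                cand[i : i + k] in hay for i in range(len(cand) - k + 1)
            )


class TestTargetingRegions:
    def test_all_emitted_regions_satisfy_constraints(self):
        transcripts = random_transcripts(6, 700, seed=3)
        trs = probes.design_targeting_regions(transcripts)
        assert len(trs) > 0
        for tr in trs:
            validate_tr(tr, transcripts, trs)

    def test_short_transcript_empty(self):
        assert probes.design_targeting_regions({"t": "ACGT" * 5}) == []

    def test_identical_transcripts_cross_hybridize(self):
        seq = random_transcripts(1, 500, seed=4)["t0"]
        trs = probes.design_targeting_regions({"a": seq, "b": seq})
        assert trs == []

    def test_background_screen(self):
        transcripts = random_transcripts(2, 600, seed=5)
        with_bg = probes.design_targeting_regions(
            {"t0": transcripts["t0"]}, background={"bg": transcripts["t0"]}
        )
        # the transcript itself supplied as background under another name
        # kills every candidate
        assert with_bg == []


class TestIndexPrimers:
    def test_run_of_four_rejected(self):
        cand = "CAGGGGCATCGATCGAGCTGCATGC"  # contains GGGG
        assert probes.select_index_primers([cand], {}) == []

    def test_weak_clamp_rejected(self):
        # final five bases ATATA: 0 G/C
        cand = "GCGTGCGATCGCAGCATATA" + "CGATC"
        assert probes.select_index_primers([cand], {}) == []

    def test_rtp_homology_rejected(self):
        # first 12 nt of the RT primer embedded in the candidate
        cand = (probes.RTP[:12] + "TTGACCAG")[:20] + "AAAAA"
        out = probes.select_index_primers([cand[:25]], {})
        assert out == []

    def test_accepted_primers_satisfy_all_filters(self, rng):
        cands = [
            "".join(rng.choice(list("ACGT"), p=[0.22, 0.28, 0.28, 0.22], size=25))
            for _ in range(4000)
        ]
        transcriptome = random_transcripts(3, 400, seed=6)
        out = probes.select_index_primers(cands, transcriptome)
        assert len(out) > 0
        screened = list(transcriptome.values()) + [probes.T7_PROMOTER, probes.RTP]
        for i, p in enumerate(out):
            others = screened + [q.sequence for q in out[:i]]
            validate_primer(p, others)


class TestTemplate:
    def test_lengths_and_rtp(self):
        tpl = probes.assemble_template("A" * 20, "ACGTTGCA" * 3 + "ACGTTG", "C" * 20)
        assert len(tpl.full_sequence) == 20 + 20 + 6 + 30 + 6 + 20
        assert probes.RTP in tpl.full_sequence

    def test_roundtrip(self):
        tr = "AC" * 15
        tpl = probes.assemble_template("ACGT" * 5, tr, "TGCA" * 5)
        parsed = probes.parse_template(tpl.full_sequence)
        assert parsed == tpl
        assert probes.revcomp(probes.revcomp(tr)) == tr

    def test_bad_part_rejected(self):
        with pytest.raises(ValueError):
            probes.assemble_template("NNNN", "AC" * 15, "C" * 20)


class TestProbeDerivation:
    @pytest.fixture()
    def template(self):
        return probes.assemble_template("A" * 20, "ACGTTGCA" * 3 + "ACGTTG", "C" * 20)

    def test_sense_contains_tr(self, template):
        probe = probes.derive_probe_sequence(template, "sense")
        assert probe.targeting_segment == template.tr

    def test_antisense_contains_rc(self, template):
        probe = probes.derive_probe_sequence(template, "antisense_control")
        assert probe.targeting_segment == probes.revcomp(template.tr)

    def test_antisense_is_rc_of_sense(self, template):
        s = probes.derive_probe_sequence(template, "sense")
        a = probes.derive_probe_sequence(template, "antisense_control")
        assert probes.revcomp(a.targeting_segment) == s.targeting_segment

    def test_unknown_mode(self, template):
        with pytest.raises(ValueError):
            probes.derive_probe_sequence(template, "nonsense")


class TestPartition:
    @pytest.fixture()
    def annotation(self):
        return pd.DataFrame(
            {
                "start": [150_000, 250_000, 350_000, 50_000, 120_000],
                "end": [151_000, 251_000, 351_000, 51_000, 121_000],
                "strand": ["+"] * 5,
                "location": ["inner membrane", "cytoplasm", "periplasm",
                             "cytoplasm", "outer membrane"],
                "copies_per_cell": [0.5, 10.0, 100.0, 0.05, 3.0],
                "operon_id": ["op1", "op1", "op2", "op3", "op2"],
            },
            index=["gIM", "gCy", "gPe", "gLow", "gOM"],
        )

    def test_abundance_ranges_half_open(self):
        assert probes.abundance_range(0.5) == "1/3-3"
        assert probes.abundance_range(3.0) == "3-30"     # boundary goes up
        assert probes.abundance_range(30.0) == "30-300"
        assert probes.abundance_range(0.1) is None
        assert probes.abundance_range(500.0) is None

    def test_location_groups(self, annotation):
        groups = {g.key: g for g in probes.partition_transcriptome(annotation)}
        assert "inner membrane|1/3-3" in groups
        assert groups["inner membrane|1/3-3"].members == ("gIM",)
        assert "unexpressed" in groups
        assert groups["unexpressed"].members == ("gLow",)
        # every expressed gene is in exactly one location x abundance group
        placed = [m for k, g in groups.items() if k != "unexpressed"
                  for m in g.members]
        assert sorted(placed) == ["gCy", "gIM", "gOM", "gPe"]

    def test_cytoplasmic_tr_third(self, annotation):
        trs = {"gCy": [f"gCy:{i}" for i in range(9)]}
        groups = probes.partition_transcriptome(annotation, trs, seed=1)
        cy = next(g for g in groups if g.key.startswith("cytoplasm"))
        assert len(cy.tr_ids) == 3

    def test_genomic_windows_alternating(self, annotation):
        groups = probes.partition_transcriptome(annotation, scheme="genomic")
        keys = {g.key: g.members for g in groups}
        assert keys.get("genomic|100-200kb") == ("gIM", "gOM")
        # gPe is 100 copies/cell -> outside the two lower ranges, excluded
        assert "genomic|300-400kb" not in keys
        # window 200-300 kb (even index 2) is skipped
        assert "genomic|200-300kb" not in keys

    def test_polycistronic_split(self, annotation):
        groups = probes.partition_transcriptome(
            annotation, split_polycistronic=True
        )
        keyed = {g.key: g.members for g in groups}
        # gCy shares operon op1 with the inner-membrane gene gIM
        assert any(
            "im-polycistronic" in k and "gCy" in v for k, v in keyed.items()
        )
        # gPe's operon op2 has no inner-membrane member
        assert any(
            "monofunctional" in k and "gPe" in v for k, v in keyed.items()
        )
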