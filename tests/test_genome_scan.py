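"""Tests for the exonic repeat scan, in-silico PCR and specificity labels."""

import numpy as np
import pytest

from ssrarch import genome_scan as gs
from ssrarch import repeat_core as rc
from ssrarch.genome_scan import PresenceMatrix, TaxonomyConfig

FAM = rc.MotifFamily({"CAG", "CAT", "CAA"})


# ---------------------------------------------------------------------------
# scan_genome
# ---------------------------------------------------------------------------


def test_scan_recovers_planted_exonic_locus_with_context(sim_dataset):
    """Every planted parental locus is found with exact span, correct gene,
    third-exon placement and in-frame CDS position."""
    _, truth, outdir = sim_dataset
    for sp in ("typhina_like", "bromicola_like"):
        loci = gs.scan_genome(
            outdir / "parents" / f"{sp}.fasta",
            outdir / "parents" / f"{sp}.gff3",
            FAM,
        )
        assert len(loci) == 1
        lc = loci[0]
        t = truth.loci[f"{sp}_chr1"]
        assert lc.span == t.span
        assert lc.arch.notation == t.notation
        assert lc.gene_id == t.gene_id
        assert lc.exon_index == 3
        assert lc.in_cds
        assert lc.frame == 0
        assert lc.strand == "+"


def test_scan_hybrids_recovers_both_alleles(sim_dataset):
    _, truth, outdir = sim_dataset
    for strain in ("U01", "U02", "U09"):
        loci = gs.scan_genome(outdir / "hybrids" / f"{strain}.fasta", None, FAM)
        assert len(loci) == 2
        for lc in loci:
            t = truth.loci[lc.contig]
            assert lc.span == t.span
            assert lc.arch.notation == t.notation


def test_scan_reverse_strand_reports_coding_orientation(sim_dataset):
    """A genomic CTG-type run (repeat on the minus strand) is reported with
    family motifs in coding orientation and mirrored coordinates."""
    _, truth, outdir = sim_dataset
    contigs = gs.load_fasta(outdir / "parents" / "typhina_like.fasta")
    (cid,) = contigs
    seq = contigs[cid]
    flipped = {cid: gs._revcomp(seq)}
    fwd_loci = gs.scan_genome(contigs, None, FAM)
    rev_loci = gs.scan_genome(flipped, None, FAM)
    assert len(fwd_loci) == len(rev_loci) == 1
    f, r = fwd_loci[0], rev_loci[0]
    assert r.strand == "-"
    assert r.arch.notation == f.arch.notation
    L = len(seq)
    assert r.span == (L - f.span[1], L - f.span[0])


def test_scan_empty_on_repeat_free_random_sequence():
    """No false loci on 10 kb of random sequence at default settings."""
    for seed in range(5):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        assert gs.scan_genome({"rand": seq}, None, FAM) == []


def test_scan_merges_interrupted_runs_into_one_composite_locus():
    # two runs separated by a single variant unit form one locus
    repeat = "CAG" * 6 + "CCG" + "CAT" * 5
    seq = "TTTTTGTTCTT" + repeat + "TTGTTCTTTTT"
    (lc,) = gs.scan_genome({"c": seq}, None, FAM)
    assert lc.span == (11, 11 + len(repeat))
    assert lc.arch.notation == "(CAG)6[CCG](CAT)5"


def test_scan_below_seed_threshold_reports_nothing():
    seq = "TTGTTCTT" + "CAG" * 4 + "TTGTTCTT"  # 4 < default seed of 5
    assert gs.scan_genome({"c": seq}, None, FAM) == []
    assert len(gs.scan_genome({"c": seq}, None, FAM, min_seed=4)) == 1


def test_scan_contig_mismatch_raises(sim_dataset, tmp_path):
    _, _, outdir = sim_dataset
    bad = tmp_path / "bad.fasta"
    bad.write_text(">other_contig\n" + "ACGT" * 30 + "\n")
    with pytest.raises(gs.ScanError, match="absent from FASTA"):
        gs.scan_genome(bad, outdir / "parents" / "typhina_like.gff3", FAM)


def test_scan_missing_cds_phase_warns_and_reports_frame_unknown(tmp_path):
    seq = "T" * 30 + "ATG" + "CAG" * 6 + "TAA" + "T" * 30
    fa = tmp_path / "g.fasta"
    fa.write_text(">c1\n" + seq + "\n")
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "c1\t.\tgene\t31\t54\t.\t+\t.\tID=g1\n"
        "c1\t.\tmRNA\t31\t54\t.\t+\t.\tID=g1.t1;Parent=g1\n"
        "c1\t.\texon\t31\t54\t.\t+\t.\tID=g1.t1.e1;Parent=g1.t1\n"
        "c1\t.\tCDS\t31\t54\t.\t+\t.\tID=g1.t1.c1;Parent=g1.t1\n"
    )
    with pytest.warns(UserWarning, match="lacks a phase"):
        (lc,) = gs.scan_genome(fa, gff, FAM)
    assert lc.in_cds
    assert lc.frame is None


# ---------------------------------------------------------------------------
# in_silico_pcr
# ---------------------------------------------------------------------------


def test_pcr_single_product_per_parent_two_per_hybrid(sim_dataset):
    _, truth, outdir = sim_dataset
    fwd, rev = truth.primers
    for sp in ("typhina_like", "bromicola_like"):
        amps = gs.in_silico_pcr(outdir / "parents" / f"{sp}.fasta", fwd, rev, family=FAM)
        assert len(amps) == 1
    amps = gs.in_silico_pcr(outdir / "hybrids" / "U01.fasta", fwd, rev, family=FAM)
    assert len(amps) == 2
    assert {a.contig for a in amps} == {"U01_typhina_like", "U01_bromicola_like"}


def test_pcr_product_structure(sim_dataset):
    _, truth, outdir = sim_dataset
    fwd, rev = truth.primers
    (amp,) = gs.in_silico_pcr(
        outdir / "parents" / "typhina_like.fasta", fwd, rev, family=FAM
    )
    assert amp.sequence.startswith(fwd)
    assert amp.sequence.endswith(gs._revcomp(rev))
    assert amp.length == len(amp.sequence)
    assert amp.arch.notation == truth.loci["typhina_like_chr1"].notation


def test_pcr_absent_primer_yields_empty_list(sim_dataset):
    _, _, outdir = sim_dataset
    amps = gs.in_silico_pcr(
        outdir / "parents" / "typhina_like.fasta", "ACGTACGTACGTACGT", "TGCATGCATGCATGCA"
    )
    assert amps == []


def test_pcr_count_invariant_to_contig_order_and_unrelated_contigs(sim_dataset):
    _, truth, outdir = sim_dataset
    fwd, rev = truth.primers
    contigs = gs.load_fasta(outdir / "hybrids" / "U01.fasta")
    n = len(gs.in_silico_pcr(contigs, fwd, rev))
    reordered = dict(reversed(list(contigs.items())))
    assert len(gs.in_silico_pcr(reordered, fwd, rev)) == n
    rng = np.random.default_rng(0)
    with_extra = {**contigs, "unrelated": "".join(rng.choice(list("ACGT"), size=2000))}
    assert len(gs.in_silico_pcr(with_extra, fwd, rev)) == n


def test_pcr_rejects_short_primers():
    with pytest.raises(ValueError, match="12"):
        gs.in_silico_pcr({"c": "ACGT" * 20}, "ACGTACGT", "ACGTACGTACGTACGT")


# ---------------------------------------------------------------------------
# classify_specificity
# ---------------------------------------------------------------------------

TAXONOMY = TaxonomyConfig(
    (
        ("Epichloe", frozenset({"Epichloe"})),
        ("Clavicipitaceae", frozenset({"Epichloe", "Claviceps", "Periglandula"})),
        (
            "Sordariomycetes",
            frozenset(
                {"Epichloe", "Claviceps", "Periglandula", "Fusarium", "Magnaporthe", "Neurospora"}
            ),
        ),
    )
)

ALL_SPECIES = sorted(TAXONOMY.broadest)


def _pm(presence: dict[str, set[str]]) -> PresenceMatrix:
    records = [
        (og, sp, sp in present) for og, present in presence.items() for sp in ALL_SPECIES
    ]
    return PresenceMatrix.from_records(records, ALL_SPECIES)


def test_specificity_labels():
    labels = gs.classify_specificity(
        _pm(
            {
                "focal_only": {"Epichloe"},
                "clavicipitaceae": {"Epichloe", "Claviceps"},
                "everywhere": set(ALL_SPECIES),
                "outside_focal": {"Fusarium", "Neurospora"},
            }
        ),
        TAXONOMY,
    )
    assert labels == {
        "focal_only": "Epichloe",
        "clavicipitaceae": "Clavicipitaceae",
        "everywhere": "Sordariomycetes",
        "outside_focal": gs.ABSENT_IN_FOCAL,
    }


def test_specificity_is_monotone_under_added_presence():
    """Adding a presence outside the current label's group can only widen
    the label (or leave it unchanged)."""
    order = {name: k for k, (name, _) in enumerate(TAXONOMY.groups)}
    present = {"Epichloe"}
    prev = gs.classify_specificity(_pm({"og": set(present)}), TAXONOMY)["og"]
    for extra in ("Claviceps", "Periglandula", "Magnaporthe"):
        present.add(extra)
        cur = gs.classify_specificity(_pm({"og": set(present)}), TAXONOMY)["og"]
        assert order[cur] >= order[prev]
        prev = cur


def test_specificity_unknown_species_is_a_config_error():
    pm = PresenceMatrix.from_records(
        [("og1", "Epichloe", True), ("og1", "Aspergillus", True)],
        ALL_SPECIES + ["Aspergillus"],
    )
    with pytest.raises(gs.SpecificityConfigError, match="Aspergillus"):
        gs.classify_specificity(pm, TAXONOMY)


def test_taxonomy_requires_strict_nesting():
    with pytest.raises(ValueError, match="strict subset"):
        TaxonomyConfig(
            (("a", frozenset({"x", "y"})), ("b", frozenset({"x", "z"})))
        )


def test_taxonomy_round_trips_through_json(tmp_path):
    path = tmp_path / "tax.json"
    path.write_text(
        '{"groups": [{"name": "Epichloe", "species": ["Epichloe"]},'
        '{"name": "Clavicipitaceae", "species": ["Epichloe", "Claviceps", "Periglandula"]}]}'
    )
    tc = TaxonomyConfig.from_json(path)
    assert tc.focal[0] == "Epichloe"
    assert tc.broadest == frozenset({"Epichloe", "Claviceps", "Periglandula"})
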