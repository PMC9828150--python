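"""Three-round filtering, two-stage assignment, EM abundances, reports."""

import numpy as np
import pandas as pd
import pytest

from chunkprof.profiler import (
    MODE_PRESETS,
    ProfileParams,
    Profiler,
    ReferenceStats,
)
from chunkprof.simulate import make_taxdump
from chunkprof.taxonomy import Taxonomy


def hits_df(rows):
    """rows: (query, target, chunkIdx, chunks, tLen, qLen, qKmers, matched)."""
    df = pd.DataFrame(
        rows,
        columns=["query", "target", "chunkIdx", "chunks", "tLen", "qLen", "qKmers", "matchedKmers"],
    )
    df["coverage"] = df["matchedKmers"] / df["qKmers"]
    return df


@pytest.fixture(scope="module")
def taxsetup(tmp_path_factory):
    """5 species; s1/s1b are two genomes of the same species."""
    taxdir = tmp_path_factory.mktemp("tax")
    names = ["s1", "s2", "s3", "s4", "s5", "s1b"]
    mapping = make_taxdump(taxdir, n_species=5, genome_names=names)
    mapping["s1b"] = mapping["s1"]
    tax = Taxonomy.from_taxdump(taxdir)
    return mapping, tax


def make_profiler(taxsetup, **kw):
    mapping, tax = taxsetup
    return Profiler(mapping, tax, ProfileParams(**kw))


def test_uniqueness_same_species_multimap(taxsetup):
    prof = make_profiler(taxsetup)
    df = prof.prepare_assignments(
        hits_df(
            [
                ("q1", "s1", 0, 10, 1000, 150, 130, 130),  # two genomes, one species
                ("q1", "s1b", 2, 10, 1000, 150, 130, 120),
                ("q2", "s1", 1, 10, 1000, 150, 130, 130),  # two species
                ("q2", "s2", 1, 10, 1000, 150, 130, 120),
                ("q3", "s3", 0, 10, 1000, 150, 130, 90),  # single hit
            ]
        )
    )
    marked = Profiler._mark_unique(df)
    uniq = marked.groupby("query")["is_uniq"].first()
    assert bool(uniq["q1"]) is True
    assert bool(uniq["q2"]) is False
    assert bool(uniq["q3"]) is True


def test_unmapped_reference_is_hard_error(taxsetup):
    prof = make_profiler(taxsetup)
    with pytest.raises(KeyError, match="ghost"):
        prof.prepare_assignments(hits_df([("q1", "ghost", 0, 10, 1000, 150, 130, 130)]))


def test_summarize_chunk_fraction_and_score(taxsetup):
    prof = make_profiler(taxsetup)
    rows = []
    # 12 unique reads spread over 4 of 10 chunks of s1
    for i in range(12):
        rows.append((f"q{i}", "s1", i % 4, 10, 1000, 150, 130, 130 - i))
    stats = prof.summarize(prof.prepare_assignments(hits_df(rows)))["s1"]
    assert stats.chunks_covered_fraction == pytest.approx(0.4)
    assert stats.n_reads == 12 and stats.n_uniq_reads == 12
    # nearest-rank 90th percentile of the 12 coverages
    covs = sorted((130 - i) / 130 for i in range(12))
    assert stats.score == pytest.approx(covs[int(np.ceil(0.9 * 12)) - 1])


def test_summarize_single_read_score(taxsetup):
    prof = make_profiler(taxsetup)
    stats = prof.summarize(
        prof.prepare_assignments(hits_df([("q", "s1", 0, 10, 1000, 150, 130, 104)]))
    )["s1"]
    assert stats.score == pytest.approx(0.8)


def test_uniform_coverage_has_small_depth_stdev(taxsetup):
    prof = make_profiler(taxsetup)
    rows = [(f"q{i}", "s1", i % 10, 10, 1000, 150, 130, 130) for i in range(100)]
    stats = prof.summarize(prof.prepare_assignments(hits_df(rows)))["s1"]
    assert stats.depth_stdev == pytest.approx(0.0, abs=1e-12)


def _stats(ref="r", taxid=100, uniq=25, hic=10, frac=1.0, reads=100, stdev=0.5):
    s = ReferenceStats(
        reference_id=ref,
        taxid=taxid,
        genome_size=1000,
        n_chunks=10,
        n_reads=reads,
        n_uniq_reads=uniq,
        n_hic_uniq_reads=hic,
        chunks_covered_fraction=frac,
        depth_stdev=stdev,
    )
    return s


def test_filter_round1_criteria(taxsetup):
    prof = make_profiler(taxsetup)
    stats = {
        "ok": _stats("ok"),
        "no_uniq": _stats("no_uniq", uniq=0, hic=0),
        "low_frac": _stats("low_frac", frac=0.7),
        "few_reads": _stats("few_reads", reads=49),
    }
    assert prof.filter_round1(stats) == {"ok"}


@pytest.mark.parametrize(
    "kw, survives",
    [
        (dict(), True),
        (dict(uniq=19), False),  # below minimum uniquely matched reads
        (dict(hic=1, uniq=40), False),  # hic count 1 < 5 and proportion 2.5% < 10%
        (dict(stdev=3.0), False),  # relative chunk-depth stdev above 2
        (dict(hic=4, uniq=80), False),  # proportion 5% < 10%
        (dict(uniq=20, hic=5), True),  # exactly at thresholds
    ],
)
def test_filter_round2_criteria(taxsetup, kw, survives):
    prof = make_profiler(taxsetup)
    stats = {"r": _stats("r", **kw)}
    assert (("r" in prof.filter_round2(stats)) is survives)


def test_two_stage_removes_explainable_reference(taxsetup):
    prof = make_profiler(taxsetup, min_uniq_reads=1)
    # every read of B also hits A; A has unique reads of its own, B none
    rows = []
    for i in range(5):
        rows.append((f"q{i}", "s1", 0, 10, 1000, 150, 130, 130))
    for i in range(3):
        rows.append((f"m{i}", "s1", 1, 10, 1000, 150, 130, 130))
        rows.append((f"m{i}", "s2", 1, 10, 1000, 150, 130, 120))
    df = prof.prepare_assignments(hits_df(rows))
    stats = prof.summarize(df)
    alive = prof.two_stage_assignment({"s1", "s2"}, stats, df)
    assert alive == {"s1"}


def test_two_stage_keeps_disjoint_and_single(taxsetup):
    prof = make_profiler(taxsetup, min_uniq_reads=1)
    rows = [("q1", "s1", 0, 10, 1000, 150, 130, 130), ("q2", "s2", 0, 10, 1000, 150, 130, 130)]
    df = prof.prepare_assignments(hits_df(rows))
    stats = prof.summarize(df)
    assert prof.two_stage_assignment({"s1", "s2"}, stats, df) == {"s1", "s2"}
    assert prof.two_stage_assignment({"s1"}, stats, df) == {"s1"}


def test_em_single_reference(taxsetup):
    prof = make_profiler(taxsetup)
    df = prof.prepare_assignments(hits_df([("q", "s1", 0, 10, 1000, 150, 130, 130)]))
    ab, iters, _ = prof.em_abundance(df)
    assert ab == {"s1": pytest.approx(1.0)}


def test_em_genome_size_normalization(taxsetup):
    # equal matched bases, genome sizes 1 Mb and 2 Mb -> abundances 2/3, 1/3
    prof = make_profiler(taxsetup)
    rows = [
        ("q1", "s1", 0, 10, 1_000_000, 150, 130, 130),
        ("q2", "s2", 0, 10, 2_000_000, 150, 130, 130),
    ]
    ab, _, _ = prof.em_abundance(prof.prepare_assignments(hits_df(rows)))
    assert ab["s1"] == pytest.approx(2 / 3)
    assert ab["s2"] == pytest.approx(1 / 3)


def test_em_symmetric_shared_reads(taxsetup):
    prof = make_profiler(taxsetup)
    rows = []
    for i in range(4):
        rows.append((f"q{i}", "s1", 0, 10, 1000, 150, 130, 130))
        rows.append((f"q{i}", "s2", 0, 10, 1000, 150, 130, 130))
    ab, _, _ = prof.em_abundance(prof.prepare_assignments(hits_df(rows)))
    assert ab["s1"] == pytest.approx(0.5)
    assert ab["s2"] == pytest.approx(0.5)


def test_em_mass_conservation_history(taxsetup):
    prof = make_profiler(taxsetup)
    rows = [
        ("q1", "s1", 0, 10, 1000, 150, 130, 130),
        ("q1", "s2", 0, 10, 2000, 150, 130, 120),
        ("q2", "s1", 1, 10, 1000, 150, 130, 130),
    ]
    ab, iters, history = prof.em_abundance(
        prof.prepare_assignments(hits_df(rows)), record_history=True
    )
    assert iters <= prof.params.em_max_iters
    for snapshot in history:
        assert sum(snapshot.values()) == pytest.approx(1.0)


def test_mode_presets_monotone():
    fields = [
        "min_chunks_fraction",
        "min_chunks_reads",
        "min_uniq_reads",
        "min_hic_uniq_reads",
        "min_hic_uniq_proportion",
    ]
    for f in fields:
        vals = [getattr(ProfileParams.from_mode(m), f) for m in range(6)]
        assert vals == sorted(vals), f
    stdevs = [ProfileParams.from_mode(m).max_chunk_depth_stdev for m in range(6)]
    assert stdevs == sorted(stdevs, reverse=True)
    assert ProfileParams.from_mode(0).keep_main_matches is True
    with pytest.raises(ValueError):
        ProfileParams.from_mode(9)


def test_full_profile_monotone_and_reports(taxsetup):
    mapping, tax = taxsetup
    prof = Profiler(mapping, tax, ProfileParams(min_chunks_reads=5, min_uniq_reads=5, min_hic_uniq_reads=2))
    rows = []
    for i in range(40):  # s1: strong, uniform
        rows.append((f"a{i}", "s1", i % 10, 10, 10_000, 150, 130, 130))
    for i in range(8):  # s2: few reads, only 3 chunks -> dies in round 1
        rows.append((f"b{i}", "s2", i % 3, 10, 10_000, 150, 130, 130))
    result = prof.profile(hits_df(rows))
    s1, s2, s3 = result.survivors
    assert s2 <= s1 and s3 <= s2
    assert set(result.abundances) == {"s1"}
    table = result.table()
    assert table.loc[0, "reference"] == "s1"
    assert table.loc[0, "abundance"] == pytest.approx(100.0)
    cami = result.cami_profile("toy")
    assert cami.startswith("@SampleID:toy")
    for rank in ("superkingdom", "genus", "species"):
        pct = [
            float(line.split("\t")[-1])
            for line in cami.splitlines()
            if not line.startswith("@") and line.split("\t")[1] == rank
        ]
        assert sum(pct) == pytest.approx(100.0, abs=1e-6)


def test_report_sorting_prefers_score_over_reads(taxsetup):
    """A high-score low-read pathogen sorts above a low-score high-read
    contaminant (sort keys: score, chunk fraction, abundance)."""
    mapping, tax = taxsetup
    prof = Profiler(mapping, tax, ProfileParams.from_mode(0))
    rows = []
    for i in range(4):  # pathogen: 4 perfect reads in 4 chunks
        rows.append((f"p{i}", "s1", i, 10, 10_000, 150, 130, 130))
    for i in range(60):  # contaminant: many mediocre reads (coverage 0.8)
        rows.append((f"c{i}", "s2", i % 10, 10, 10_000, 150, 130, 104))
    result = prof.profile(hits_df(rows))
    table = result.table()
    assert set(table["reference"]) == {"s1", "s2"}
    # s1's score (1.0) beats s2's (0.8): s1 comes first despite 15x fewer reads
    assert table.loc[0, "reference"] == "s1"
    assert table.loc[0, "reads"] < table.loc[1, "reads"]


def test_two_species_one_genus_cami_aggregation(taxsetup):
    mapping, tax = taxsetup
    # species taxids 100..104 sit in 1 genus round-robin when n_genera=1
    prof = Profiler(mapping, tax, ProfileParams(min_chunks_reads=1, min_uniq_reads=1, min_hic_uniq_reads=1))
    rows = []
    for i in range(30):
        rows.append((f"a{i}", "s1", i % 10, 10, 10_000, 150, 130, 130))
    for i in range(20):
        rows.append((f"b{i}", "s2", i % 10, 10, 10_000, 150, 130, 130))
    result = prof.profile(hits_df(rows))
    genus = result.rank_abundances("genus")
    assert sum(genus.values()) == pytest.approx(1.0)
    species = result.rank_abundances("species")
    assert species[100] == pytest.approx(0.6, abs=0.02)
    assert species[101] == pytest.approx(0.4, abs=0.02)


def test_empty_profile(taxsetup):
    prof = make_profiler(taxsetup)
    result = prof.profile(hits_df([]))
    assert result.abundances == {}
    assert result.table().empty
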