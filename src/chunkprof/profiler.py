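"""Taxonomic profiling from merged search hits.

Homologous regions shared across species make single-read evidence
unreliable, so presence calls combine k-mer similarity with genome-chunk
coverage evidence.  A three-round filter removes suspicious references:

* round 1 (loose): a reference needs (i) at least one uniquely matched
  read, (ii) at least one high-confidence (coverage >= 0.75) uniquely
  matched read, (iii) a minimum fraction of its genome chunks covered
  and (iv) a minimum number of matched reads;
* round 2: reads are reassigned among round-1 survivors and criteria
  (i)-(iv) reapply with stricter read counts, plus (v) a cap on the
  standard deviation of relative chunk depths and (vi) a minimum
  proportion of high-confidence uniquely matched reads; a two-stage
  assignment pass then absorbs references explainable by better ones;
* round 3: reads are reassigned again (reads all of whose references
  were filtered out are excluded) and the round-2 criteria reapply
  without the two-stage pass.

A read matching several genomes of one species still counts as uniquely
matched.  Relative abundances of the final references are estimated by
EM: multi-mapped read mass is split in proportion to current
genome-size-normalized abundances and re-estimated until the
predominant genome's abundance changes by less than a tolerance or an
iteration cap is reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chunkprof.taxonomy import CANONICAL_RANKS, Taxonomy


@dataclass
class ProfileParams:
    """Thresholds of the three-round filter and the EM estimator.

    ``min_chunks_fraction`` is the fraction of genome chunks that must
    hold at least one read; ``min_chunks_reads`` is the minimum total
    matched reads per reference.  ``min_uniq_reads`` /
    ``min_hic_uniq_reads`` apply from round 2 on (round 1 requires one
    of each).  ``hic_cov`` is the high-confidence coverage bound
    (roughly 98% identity).  ``keep_main_matches`` drops per-read
    matches with sharply lower coverage than the best match before
    profiling (pathogen mode).
    """

    mode: int = 3
    min_query_cov: float = 0.55
    hic_cov: float = 0.75
    min_chunks_fraction: float = 0.8
    min_chunks_reads: int = 50
    min_uniq_reads: int = 20
    min_hic_uniq_reads: int = 5
    max_chunk_depth_stdev: float = 2.0
    min_hic_uniq_proportion: float = 0.10
    em_max_iters: int = 10
    em_tol: float = 0.01
    keep_main_matches: bool = False
    main_match_gap: float = 0.2

    def __post_init__(self) -> None:
        for name in ("min_chunks_fraction", "min_hic_uniq_proportion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "min_chunks_reads",
            "min_uniq_reads",
            "min_hic_uniq_reads",
            "max_chunk_depth_stdev",
            "em_max_iters",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_mode(cls, mode: int) -> "ProfileParams":
        if mode not in MODE_PRESETS:
            raise ValueError(f"unknown profiling mode {mode}")
        return cls(mode=mode, **MODE_PRESETS[mode])


# Preset thresholds per mode, loose (0, pathogen detection) to strict
# (5, higher precision).  Mode 0 requires only 2 of 10 chunks covered
# with one read each and switches the main-matches flag on; mode 3 is
# the default.  Intermediate values scale the round thresholds
# monotonically between the two documented anchors.
MODE_PRESETS: dict[int, dict] = {
    0: dict(
        min_chunks_fraction=0.2,
        min_chunks_reads=1,
        min_uniq_reads=1,
        min_hic_uniq_reads=1,
        max_chunk_depth_stdev=10.0,
        min_hic_uniq_proportion=0.0,
        keep_main_matches=True,
    ),
    1: dict(
        min_chunks_fraction=0.4,
        min_chunks_reads=10,
        min_uniq_reads=5,
        min_hic_uniq_reads=2,
        max_chunk_depth_stdev=4.0,
        min_hic_uniq_proportion=0.05,
    ),
    2: dict(
        min_chunks_fraction=0.6,
        min_chunks_reads=30,
        min_uniq_reads=10,
        min_hic_uniq_reads=3,
        max_chunk_depth_stdev=3.0,
        min_hic_uniq_proportion=0.08,
    ),
    3: dict(),  # documented defaults
    4: dict(
        min_chunks_fraction=0.9,
        min_chunks_reads=80,
        min_uniq_reads=30,
        min_hic_uniq_reads=10,
        max_chunk_depth_stdev=1.5,
        min_hic_uniq_proportion=0.15,
    ),
    5: dict(
        min_chunks_fraction=0.95,
        min_chunks_reads=100,
        min_uniq_reads=50,
        min_hic_uniq_reads=20,
        max_chunk_depth_stdev=1.0,
        min_hic_uniq_proportion=0.20,
    ),
}


@dataclass
class ReferenceStats:
    """Per-reference evidence summary feeding the three-round filter."""

    reference_id: str
    taxid: int
    genome_size: int
    n_chunks: int
    n_reads: int = 0
    n_uniq_reads: int = 0
    n_hic_uniq_reads: int = 0
    chunks_covered_fraction: float = 0.0
    chunk_read_counts: dict[int, int] = field(default_factory=dict)
    depth_stdev: float = 0.0
    matched_bases: float = 0.0
    score: float = 0.0

    @property
    def hic_uniq_proportion(self) -> float:
        return self.n_hic_uniq_reads / self.n_uniq_reads if self.n_uniq_reads else 0.0


@dataclass
class ProfileResult:
    params: ProfileParams
    stats: dict[str, ReferenceStats]
    abundances: dict[str, float]
    survivors: list[set[str]]  # after rounds 1, 2 (incl. two-stage), 3
    assignments: pd.DataFrame  # final per-(query, reference) best hits
    em_iters: int
    taxonomy: Taxonomy
    taxid_map: dict[str, int]

    def table(self) -> pd.DataFrame:
        """Report rows sorted by (score, chunk fraction, abundance) desc."""
        rows = []
        for ref, ab in self.abundances.items():
            s = self.stats[ref]
            taxid = self.taxid_map[ref]
            node = self.taxonomy.nodes[self.taxonomy.resolve(taxid)]
            lineage = self.taxonomy.lineage(taxid)
            lineage_str = ";".join(
                lineage[r][1] for r in CANONICAL_RANKS if r in lineage
            )
            rows.append(
                {
                    "reference": ref,
                    "taxid": taxid,
                    "rank": node.rank,
                    "taxname": node.name,
                    "lineage": lineage_str,
                    "abundance": round(100.0 * ab, 3),
                    "reads": s.n_reads,
                    "uniq_reads": s.n_uniq_reads,
                    "hic_uniq_reads": s.n_hic_uniq_reads,
                    "chunks_fraction": s.chunks_covered_fraction,
                    "score": s.score,
                }
            )
        df = pd.DataFrame(rows)
        if len(df):
            df = df.sort_values(
                ["score", "chunks_fraction", "abundance"],
                ascending=False,
                kind="mergesort",
            ).reset_index(drop=True)
        return df

    def rank_abundances(self, rank: str) -> dict[int, float]:
        """Abundance aggregated to ``rank``, normalized to sum 1."""
        agg: dict[int, float] = {}
        for ref, ab in self.abundances.items():
            anc = self.taxonomy.rank_ancestor(self.taxid_map[ref], rank)
            if anc is not None:
                agg[anc] = agg.get(anc, 0.0) + ab
        total = sum(agg.values())
        if total > 0:
            agg = {t: v / total for t, v in agg.items()}
        return agg

    def cami_profile(self, sample_id: str = "sample") -> str:
        """CAMI profiling format (OPAL-compatible); per-rank sums are 100."""
        lines = [
            f"@SampleID:{sample_id}",
            "@Version:0.9.4",
            "@Ranks:" + "|".join(CANONICAL_RANKS),
            "@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE",
        ]
        for rank in CANONICAL_RANKS:
            agg = self.rank_abundances(rank)
            for taxid in sorted(agg, key=lambda t: -agg[t]):
                lineage = self.taxonomy.lineage(taxid)
                upto = CANONICAL_RANKS[: CANONICAL_RANKS.index(rank) + 1]
                ids = [str(lineage[r][0]) for r in upto if r in lineage]
                names = [lineage[r][1] for r in upto if r in lineage]
                lines.append(
                    f"{taxid}\t{rank}\t{'|'.join(ids)}\t{'|'.join(names)}\t"
                    f"{100.0 * agg[taxid]:.6f}"
                )
        return "\n".join(lines) + "\n"


class Profiler:
    """Turns a merged search hit table into a taxonomic profile."""

    def __init__(
        self,
        taxid_map: dict[str, int],
        taxonomy: Taxonomy,
        params: ProfileParams | None = None,
    ):
        self.taxid_map = taxid_map
        self.taxonomy = taxonomy
        self.params = params or ProfileParams()

    # -- read assignment ----------------------------------------------------

    def prepare_assignments(self, hits: pd.DataFrame) -> pd.DataFrame:
        """Best hit per (query, reference) with taxid/species annotations.

        References missing from the TaxId map are a hard error (the map
        must cover everything that was indexed).
        """
        refs = hits["target"].unique()
        missing = sorted(r for r in refs if r not in self.taxid_map)
        if missing:
            raise KeyError(f"references absent from TaxId map: {missing}")
        df = hits.copy()
        if self.params.keep_main_matches and len(df):
            best = df.groupby("query")["coverage"].transform("max")
            df = df[df["coverage"] >= best - self.params.main_match_gap]
        df = (
            df.sort_values(
                ["coverage", "matchedKmers", "chunkIdx"],
                ascending=[False, False, True],
                kind="mergesort",
            )
            .drop_duplicates(["query", "target"])
            .copy()
        )
        species = {}
        for ref in refs:
            taxid = self.taxonomy.resolve(self.taxid_map[ref])
            species[ref] = self.taxonomy.species_of(taxid) or taxid
        df["species"] = df["target"].map(species)
        df["bases"] = df["qLen"] * df["coverage"]
        return df.reset_index(drop=True)

    @staticmethod
    def _mark_unique(df: pd.DataFrame) -> pd.DataFrame:
        """A query is uniquely matched iff all candidates share one species."""
        n_species = df.groupby("query")["species"].transform("nunique")
        df = df.copy()
        df["is_uniq"] = n_species == 1
        return df

    # -- evidence summary ---------------------------------------------------

    def summarize(self, df: pd.DataFrame) -> dict[str, ReferenceStats]:
        df = self._mark_unique(df)
        stats: dict[str, ReferenceStats] = {}
        for ref, grp in df.groupby("target", sort=True):
            taxid = self.taxid_map[str(ref)]
            n_chunks = int(grp["chunks"].iloc[0])
            genome_size = int(grp["tLen"].iloc[0])
            uniq = grp[grp["is_uniq"]]
            chunk_counts = grp.groupby("chunkIdx").size().to_dict()
            chunk_bases = grp.groupby("chunkIdx")["bases"].sum()
            rel = chunk_bases / chunk_bases.mean() if len(chunk_bases) else chunk_bases
            depth_stdev = float(rel.std(ddof=0)) if len(rel) > 1 else 0.0
            covs = np.sort(uniq["coverage"].to_numpy())
            score = float(covs[math.ceil(0.9 * covs.size) - 1]) if covs.size else 0.0
            stats[str(ref)] = ReferenceStats(
                reference_id=str(ref),
                taxid=taxid,
                genome_size=genome_size,
                n_chunks=n_chunks,
                n_reads=int(len(grp)),
                n_uniq_reads=int(len(uniq)),
                n_hic_uniq_reads=int((uniq["coverage"] >= self.params.hic_cov).sum()),
                chunks_covered_fraction=len(chunk_counts) / n_chunks,
                chunk_read_counts={int(k): int(v) for k, v in chunk_counts.items()},
                depth_stdev=depth_stdev,
                matched_bases=float(grp["bases"].sum()),
                score=score,
            )
        return stats

    # -- filter rounds ------------------------------------------------------

    def filter_round1(self, stats: dict[str, ReferenceStats]) -> set[str]:
        p = self.params
        return {
            r
            for r, s in stats.items()
            if s.n_uniq_reads >= 1
            and s.n_hic_uniq_reads >= 1
            and s.chunks_covered_fraction >= p.min_chunks_fraction
            and s.n_reads >= p.min_chunks_reads
        }

    def _strict_criteria(self, s: ReferenceStats) -> bool:
        p = self.params
        return (
            s.n_uniq_reads >= p.min_uniq_reads
            and s.n_hic_uniq_reads >= p.min_hic_uniq_reads
            and s.chunks_covered_fraction >= p.min_chunks_fraction
            and s.n_reads >= p.min_chunks_reads
            and s.depth_stdev <= p.max_chunk_depth_stdev
            and s.hic_uniq_proportion >= p.min_hic_uniq_proportion
        )

    def filter_round2(self, stats: dict[str, ReferenceStats]) -> set[str]:
        return {r for r, s in stats.items() if self._strict_criteria(s)}

    filter_round3 = filter_round2  # same predicate, no two-stage pass after

    def two_stage_assignment(
        self, survivors: set[str], stats: dict[str, ReferenceStats], df: pd.DataFrame
    ) -> set[str]:
        """Absorb references whose multi-mapped reads a better reference explains.

        Stage 1 ranks survivors by uniquely-matched reads (descending,
        ties broken by reference id for determinism).  Stage 2 walks the
        ranking from weakest to strongest and removes a reference when
        every one of its multi-mapped reads also hits a strictly
        higher-ranked surviving reference and it has fewer than
        ``min_uniq_reads`` uniquely matched reads of its own.
        """
        order = sorted(survivors, key=lambda r: (-stats[r].n_uniq_reads, r))
        rank = {r: i for i, r in enumerate(order)}
        df = df[df["target"].isin(survivors)]
        cand = df.groupby("query")["target"].apply(set)
        by_ref: dict[str, list[set[str]]] = {r: [] for r in survivors}
        for refs in cand:
            for r in refs:
                by_ref[r].append(refs)
        alive = set(survivors)
        for r in reversed(order):
            if stats[r].n_uniq_reads >= self.params.min_uniq_reads:
                continue
            multi = [refs for refs in by_ref[r] if len(refs) > 1]
            if not multi:
                continue
            explainable = all(
                any(o in alive and rank[o] < rank[r] for o in refs if o != r)
                for refs in multi
            )
            own_unique = any(len(refs) == 1 for refs in by_ref[r])
            if explainable and not own_unique:
                alive.discard(r)
        return alive

    # -- EM abundance -------------------------------------------------------

    def em_abundance(
        self, df: pd.DataFrame, record_history: bool = False
    ) -> tuple[dict[str, float], int, list[dict[str, float]]]:
        """Genome-size-normalized abundances of the final references.

        Each read's matched bases are split across its candidate
        references (equally at initialization, then in proportion to the
        abundances of the previous iteration); the abundance of a
        reference is its assigned base mass divided by its genome size,
        normalized to sum 1.  Iteration stops after ``em_max_iters``
        rounds or when the predominant reference's abundance changes by
        less than ``em_tol`` (relative).  Each read's fractional
        assignment weights always sum to one (mass conservation).
        """
        if not len(df):
            return {}, 0, []
        refs = sorted(df["target"].unique())
        gsize = df.groupby("target")["tLen"].first().astype(float)
        work = df[["query", "target", "bases"]].copy()
        ncand = work.groupby("query")["target"].transform("size")
        work["w"] = 1.0 / ncand

        def estimate() -> pd.Series:
            mass = (work["w"] * work["bases"]).groupby(work["target"]).sum()
            mass = mass.reindex(refs, fill_value=0.0)
            ab = mass / gsize.reindex(refs)
            total = ab.sum()
            return ab / total if total > 0 else ab

        abundance = estimate()
        history = [abundance.to_dict()] if record_history else []
        iters = 0
        for _ in range(self.params.em_max_iters):
            iters += 1
            prev_top = float(abundance.max())
            work["a"] = work["target"].map(abundance)
            denom = work.groupby("query")["a"].transform("sum")
            work["w"] = np.where(denom > 0, work["a"] / denom, work["w"])
            per_read = work.groupby("query")["w"].sum()
            if not np.allclose(per_read.to_numpy(), 1.0, atol=1e-9):
                raise AssertionError("EM read mass not conserved")
            abundance = estimate()
            if record_history:
                history.append(abundance.to_dict())
            top = float(abundance.max())
            if prev_top > 0 and abs(top - prev_top) / prev_top < self.params.em_tol:
                break
        return abundance.to_dict(), iters, history

    # -- full pipeline ------------------------------------------------------

    def profile(self, hits: pd.DataFrame) -> ProfileResult:
        df = self.prepare_assignments(hits)
        survivors_log: list[set[str]] = []

        stats = self.summarize(df)
        s1 = self.filter_round1(stats)
        survivors_log.append(set(s1))

        df2 = df[df["target"].isin(s1)]
        stats2 = self.summarize(df2)
        s2 = self.filter_round2(stats2)
        s2 = self.two_stage_assignment(s2, stats2, df2)
        survivors_log.append(set(s2))

        df3 = df2[df2["target"].isin(s2)]
        stats3 = self.summarize(df3)
        s3 = self.filter_round3(stats3)
        survivors_log.append(set(s3))

        final_df = df3[df3["target"].isin(s3)].reset_index(drop=True)
        final_stats = {r: s for r, s in self.summarize(final_df).items()} if len(final_df) else {}
        abundances, em_iters, _ = self.em_abundance(final_df)
        return ProfileResult(
            params=self.params,
            stats=final_stats,
            abundances=abundances,
            survivors=survivors_log,
            assignments=final_df,
            em_iters=em_iters,
            taxonomy=self.taxonomy,
            taxid_map=self.taxid_map,
        )
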