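"""Homology-aware train/validation/test splitting by cluster expansion.

Cross-validation on protein classifiers is only honest when homologous
sequences never straddle a train/test boundary. The procedure here:

1. cluster each class at 40% identity with a greedy incremental
   clusterer (CD-HIT-style: longest sequence founds a cluster, later
   sequences join the first representative they match at threshold);
2. randomly partition the cluster representatives of each class into
   11 equal-size subsets (10 cross-validation sets plus a test set);
3. expand each subset by replacing every representative with its full
   cluster, so all sequence diversity is retained while homologs stay
   within one set;
4. merge the per-class subsets into the global sets 1D-10D and TEST
   and remove byte-identical duplicates;
5. the background ("others") corpus is first purged of any sequence
   that co-clusters at 60% identity with a class sequence, then split
   the same way.

Pairwise identity is matched columns divided by alignment length,
under a global alignment scored match +1 / mismatch 0 with affine gaps
(open -10, extend -0.5) — the heavy gap-open cost keeps alignments of
unrelated sequences from scavenging spurious matches through scattered
gaps. This denominator differs from CD-HIT's shorter-sequence length;
on gap-free homologous families the two agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from phagenn.seqio import ProteinRecord

logger = logging.getLogger(__name__)

SET_NAMES = tuple(f"{i}D" for i in range(1, 11)) + ("TEST",)


@dataclass(frozen=True)
class Cluster:
    representative_id: str
    member_ids: tuple[str, ...]
    class_label: str


@dataclass(frozen=True)
class SplitConfig:
    cluster_identity: float = 0.40
    purge_identity: float = 0.60
    n_validation_sets: int = 10
    rng_seed: int = 0
    #: expand=False keeps only representatives (the unexpanded baseline).
    expand: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.cluster_identity <= 1:
            raise ValueError("cluster_identity must be in (0, 1]")
        if not 0 < self.purge_identity <= 1:
            raise ValueError("purge_identity must be in (0, 1]")
        if self.n_validation_sets < 1:
            raise ValueError("need at least one validation set")

    @property
    def set_names(self) -> tuple[str, ...]:
        return tuple(f"{i}D" for i in range(1, self.n_validation_sets + 1)) + ("TEST",)


@dataclass
class SplitAssignment:
    """Mapping of every retained sequence to one disjoint set."""

    set_of: dict[str, str]
    cluster_of: dict[str, Cluster]
    config: SplitConfig
    #: per class: {"raw": ..., "clusters": ..., "retained": ...}
    audit: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def set_names(self) -> tuple[str, ...]:
        return self.config.set_names

    def ids_in(self, *sets: str) -> list[str]:
        wanted = set(sets)
        return [i for i, s in self.set_of.items() if s in wanted]

    def to_manifest(self, path: str | Path) -> None:
        """Write `id<TAB>class<TAB>cluster_rep<TAB>set`."""
        with open(path, "w") as fh:
            fh.write("id\tclass\tcluster_rep\tset\n")
            for rec_id in sorted(self.set_of):
                cl = self.cluster_of[rec_id]
                fh.write(f"{rec_id}\t{cl.class_label}\t{cl.representative_id}\t{self.set_of[rec_id]}\n")

    def audit_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("class,raw,after_40pct_dereplication,after_expansion_and_100pct_dereplication\n")
            for cls, row in self.audit.items():
                fh.write(f"{cls},{row['raw']},{row['clusters']},{row['retained']}\n")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matched columns / alignment length.

    The alignment is scored match +1, mismatch 0, affine gaps (open
    -10, extend -0.5); the scoring only shapes the alignment, identity
    is read off its columns. Symmetric, and 1.0 for identical
    sequences.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0
    aln = _ALIGNER.align(a, b)[0]
    return aln.counts().identities / aln.length


def identity_at_least(a: str, b: str, threshold: float) -> bool:
    """Threshold test with a cheap length prefilter: identity cannot
    exceed len_short / len_long, so very unequal lengths skip the
    alignment entirely."""
    short, long_ = (len(a), len(b)) if len(a) <= len(b) else (len(b), len(a))
    if short / long_ < threshold:
        return False
    return pairwise_identity(a, b) >= threshold


def greedy_cluster(
    records: Sequence[ProteinRecord],
    threshold: float,
    class_label: str | None = None,
) -> list[Cluster]:
    """CD-HIT-style greedy incremental clustering.

    Sequences are sorted by descending length (ties by id); each joins
    the first existing cluster whose representative it matches at >=
    threshold, otherwise it founds a new cluster. Every record lands in
    exactly one cluster; representatives are the longest members.
    """
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[ProteinRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        placed = False
        for ci, rep in enumerate(reps):
            if identity_at_least(rec.sequence, rep.sequence, threshold):
                members[ci].append(rec.id)
                placed = True
                break
        if not placed:
            reps.append(rec)
            members.append([rec.id])
    label = class_label
    if label is None:
        labels = {r.label for r in records if r.label is not None}
        label = labels.pop() if len(labels) == 1 else ""
    return [
        Cluster(representative_id=rep.id, member_ids=tuple(mem), class_label=label)
        for rep, mem in zip(reps, members)
    ]


def partition_representatives(
    clusters: Sequence[Cluster],
    n_sets: int,
    rng_seed: int,
    set_names: Sequence[str] | None = None,
) -> dict[str, str]:
    """Shuffle clusters with a seeded generator and deal them round-robin
    into n_sets, so per-set cluster counts differ by at most one.

    Returns representative_id -> set name.
    """
    if set_names is None:
        set_names = tuple(f"{i}D" for i in range(1, n_sets)) + ("TEST",)
    if len(set_names) != n_sets:
        raise ValueError("set_names length must equal n_sets")
    if len(clusters) < n_sets:
        logger.warning(
            "only %d clusters for %d sets; some sets will be empty for this class",
            len(clusters), n_sets,
        )
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(clusters))
    # random starting set so that when cluster counts are not a
    # multiple of n_sets the surplus lands on random sets, not
    # systematically on the first ones
    offset = int(rng.integers(n_sets))
    return {
        clusters[ci].representative_id: set_names[(pos + offset) % n_sets]
        for pos, ci in enumerate(order)
    }


def expand_partition(
    clusters: Sequence[Cluster],
    rep_to_set: Mapping[str, str],
    config: SplitConfig,
) -> tuple[dict[str, str], dict[str, Cluster]]:
    """Every cluster member inherits its representative's set. With
    config.expand False only representatives are retained."""
    set_of: dict[str, str] = {}
    cluster_of: dict[str, Cluster] = {}
    for cl in clusters:
        s = rep_to_set[cl.representative_id]
        ids = cl.member_ids if config.expand else (cl.representative_id,)
        for rec_id in ids:
            set_of[rec_id] = s
            cluster_of[rec_id] = cl
    return set_of, cluster_of


def dedup_exact(assignment: SplitAssignment, records: Mapping[str, ProteinRecord]) -> SplitAssignment:
    """Remove byte-identical duplicate sequences, keeping the first
    survivor by (set order, id order)."""
    set_rank = {s: i for i, s in enumerate(assignment.set_names)}
    ids = sorted(
        assignment.set_of,
        key=lambda i: (set_rank[assignment.set_of[i]], i),
    )
    seen: dict[str, str] = {}
    removed = 0
    new_set_of: dict[str, str] = {}
    new_cluster_of: dict[str, Cluster] = {}
    for rec_id in ids:
        seq = records[rec_id].sequence
        if seq in seen:
            removed += 1
            continue
        seen[seq] = rec_id
        new_set_of[rec_id] = assignment.set_of[rec_id]
        new_cluster_of[rec_id] = assignment.cluster_of[rec_id]
    if removed:
        logger.info("dedup_exact removed %d identical sequences", removed)
    return SplitAssignment(
        set_of=new_set_of,
        cluster_of=new_cluster_of,
        config=assignment.config,
        audit=assignment.audit,
    )


def purge_cross_homologs(
    others: Sequence[ProteinRecord],
    classes: Sequence[ProteinRecord],
    threshold: float = 0.60,
) -> list[ProteinRecord]:
    """Drop background sequences homologous to any class sequence.

    Both corpora are co-clustered at the threshold; only background
    records whose cluster contains no class record are kept.
    """
    if not classes:
        return list(others)
    class_ids = {r.id for r in classes}
    clusters = greedy_cluster(list(others) + list(classes), threshold, class_label="")
    keep: set[str] = set()
    for cl in clusters:
        if not any(m in class_ids for m in cl.member_ids):
            keep.update(cl.member_ids)
    kept = [r for r in others if r.id in keep]
    logger.info("purge_cross_homologs removed %d of %d background sequences",
                len(others) - len(kept), len(others))
    return kept


def build_split(
    class_corpora: Mapping[str, Sequence[ProteinRecord]],
    others: Sequence[ProteinRecord] = (),
    config: SplitConfig = SplitConfig(),
    others_label: str = "others",
) -> SplitAssignment:
    """Run the full cluster-expansion split over all classes.

    The background corpus is purged of cross-homologs first, then every
    class (background included) is clustered, partitioned, expanded,
    merged, and finally de-replicated at 100%. The audit table records
    per-class counts at each stage.
    """
    for cls, recs in class_corpora.items():
        if not recs:
            raise ValueError(f"class {cls!r} has zero sequences")

    all_class_records = [r for recs in class_corpora.values() for r in recs]
    corpora: dict[str, Sequence[ProteinRecord]] = dict(class_corpora)
    if others:
        corpora[others_label] = purge_cross_homologs(
            others, all_class_records, config.purge_identity
        )

    n_sets = config.n_validation_sets + 1
    rng = np.random.default_rng(config.rng_seed)
    set_of: dict[str, str] = {}
    cluster_of: dict[str, Cluster] = {}
    audit: dict[str, dict[str, int]] = {}
    records_by_id: dict[str, ProteinRecord] = {}
    for cls in corpora:
        recs = corpora[cls]
        for r in recs:
            if r.id in records_by_id:
                raise ValueError(f"duplicate record id across corpora: {r.id!r}")
            records_by_id[r.id] = r
        clusters = greedy_cluster(recs, config.cluster_identity, class_label=cls)
        class_seed = int(rng.integers(0, 2**31 - 1))
        rep_to_set = partition_representatives(
            clusters, n_sets, class_seed, set_names=config.set_names
        )
        cls_sets, cls_clusters = expand_partition(clusters, rep_to_set, config)
        set_of.update(cls_sets)
        cluster_of.update(cls_clusters)
        audit[cls] = {"raw": len(recs), "clusters": len(clusters), "retained": 0}

    assignment = SplitAssignment(set_of=set_of, cluster_of=cluster_of, config=config, audit=audit)
    assignment = dedup_exact(assignment, records_by_id)
    for rec_id in assignment.set_of:
        audit[assignment.cluster_of[rec_id].class_label]["retained"] += 1
    return assignment
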