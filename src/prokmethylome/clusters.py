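"""Runs of adjacent unmethylated motifs and their permutation significance.

A cluster is a run of at least 3 consecutive unmethylated motifs (consecutive
in the contig-ordered instance list — an intervening methylated, ambiguous or
low-coverage instance breaks the run), each separated from its neighbour by
strictly less than the genome-wide mean inter-motif distance.

Significance comes from a Monte-Carlo null that keeps the real motif
positions fixed: each iteration draws n of the l instance indices without
replacement as "unmethylated", re-applies the full cluster criterion, and
records whether any cluster of at least the observed size appears.  The
Laplace (add-one) estimator keeps p away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .calling import MethylationCall
from .io_formats import PipelineConfig
from .motifs import MotifInstance


@dataclass
class ClusterResult:
    contig_id: str
    member_instances: list[MotifInstance]
    k: int
    span: int
    l: int  # total motif instances on the contig
    n: int  # total unmethylated instances on the contig
    p_value: Optional[float] = None
    n_permutations: int = 0
    seed: Optional[int] = None

    @property
    def start(self) -> int:
        return self.member_instances[0].start

    @property
    def end(self) -> int:
        return self.member_instances[-1].end


def _runs_of_true(chosen: np.ndarray, gap_ok: np.ndarray, min_size: int):
    """Maximal runs of consecutive chosen indices whose linking gaps qualify.

    chosen: bool (l,); gap_ok: bool (l-1,) — gap between index i and i+1.
    Yields (start_index, run_length) for runs of length >= min_size.
    """
    l = chosen.size
    i = 0
    while i < l:
        if not chosen[i]:
            i += 1
            continue
        j = i
        while j + 1 < l and chosen[j + 1] and gap_ok[j]:
            j += 1
        if j - i + 1 >= min_size:
            yield i, j - i + 1
        i = j + 1


def find_unmethylated_clusters(calls: list[MethylationCall], mean_gap: float,
                               cfg: PipelineConfig | None = None) -> list[ClusterResult]:
    """Detect maximal qualifying runs of unmethylated calls (p-values unset)."""
    cfg = cfg or PipelineConfig()
    if not calls:
        return []
    calls = sorted(calls, key=lambda c: c.instance.start)
    starts = np.array([c.instance.start for c in calls], dtype=np.int64)
    chosen = np.array([c.state == "unmethylated" for c in calls])
    gap_ok = np.diff(starts) < mean_gap  # strict: equal spacing never clusters
    contig = calls[0].instance.contig_id
    n_unmeth = int(chosen.sum())
    out = []
    for i, size in _runs_of_true(chosen, gap_ok, cfg.cluster_min_size):
        members = [calls[j].instance for j in range(i, i + size)]
        out.append(
            ClusterResult(
                contig_id=contig, member_instances=members, k=size,
                span=members[-1].end - members[0].start,
                l=len(calls), n=n_unmeth,
            )
        )
    return out


def _null_success_rate(starts: np.ndarray, mean_gap: float, n: int, k: int,
                       iters: int, rng: np.random.Generator,
                       min_size: int) -> int:
    """Number of null draws containing a qualifying run of size >= k."""
    l = starts.size
    gap_ok = np.diff(starts) < mean_gap
    # Vectorised draws: argpartition of uniform noise gives n random indices
    # per iteration without replacement.
    noise = rng.random((iters, l))
    order = np.argpartition(noise, n - 1, axis=1)[:, :n]
    chosen = np.zeros((iters, l), dtype=bool)
    rows = np.repeat(np.arange(iters), n)
    chosen[rows, order.ravel()] = True
    k_eff = max(k, min_size)
    # A run of k_eff members needs k_eff-1 consecutive qualifying links where
    # both flanking indices are chosen.
    links = chosen[:, :-1] & chosen[:, 1:] & gap_ok[None, :]
    w = k_eff - 1
    if w <= 0:
        return int(chosen.any(axis=1).sum())
    if links.shape[1] < w:
        return 0
    windows = np.lib.stride_tricks.sliding_window_view(links, w, axis=1)
    success = windows.all(axis=2).any(axis=1)
    return int(success.sum())


def cluster_permutation_pvalue(cluster: ClusterResult,
                               instance_positions, n: int | None = None,
                               iters: int | None = None,
                               seed: int | None = None,
                               mean_gap: float | None = None,
                               cfg: PipelineConfig | None = None) -> float:
    """Monte-Carlo p for observing a cluster of size >= k under random labelling.

    p = (1 + successes) / (1 + iterations); significant at p <= 0.01.
    """
    cfg = cfg or PipelineConfig()
    starts = np.sort(np.asarray(
        [p.start if isinstance(p, MotifInstance) else p for p in instance_positions],
        dtype=np.int64))
    l = starts.size
    n = cluster.n if n is None else n
    if n > l:
        raise ValueError(f"n={n} exceeds total instances l={l}")
    iters = cfg.n_permutations if iters is None else iters
    if mean_gap is None:
        if l < 2:
            raise ValueError("need >= 2 instances for a mean gap")
        mean_gap = float(np.diff(starts).mean())
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    # Chunk iterations to bound the (iters x l) boolean workspace.
    chunk = max(1, min(iters, int(2e7 // max(l, 1))))
    successes = 0
    done = 0
    while done < iters:
        m = min(chunk, iters - done)
        successes += _null_success_rate(starts, mean_gap, n, cluster.k, m, rng,
                                        cfg.cluster_min_size)
        done += m
    p = (1 + successes) / (1 + iters)
    cluster.p_value = p
    cluster.n_permutations = iters
    cluster.seed = seed
    return p


def enumerate_cluster_pvalue(starts, n: int, k: int,
                             mean_gap: float | None = None,
                             min_size: int = 3) -> float:
    """Exact null probability by full enumeration of C(l, n) labellings.

    Tractable for small l; the permutation estimate converges to this value.
    """
    from itertools import combinations

    starts = np.sort(np.asarray(starts, dtype=np.int64))
    l = starts.size
    if mean_gap is None:
        mean_gap = float(np.diff(starts).mean())
    gap_ok = np.diff(starts) < mean_gap
    k_eff = max(k, min_size)
    total = success = 0
    for combo in combinations(range(l), n):
        total += 1
        chosen = np.zeros(l, dtype=bool)
        chosen[list(combo)] = True
        if any(size >= k_eff for _, size in _runs_of_true(chosen, gap_ok, k_eff)):
            success += 1
    return success / total
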