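"""Resolvable incomplete block (alpha) designs.

An alpha design partitions each of ``r`` complete replicates of ``t``
treatments into ``b`` incomplete blocks of ``k`` plots (``t = b*k``).  Every
treatment occurs exactly once per replicate and never twice in a block, so
blocks can be modelled as random effects nested in replicates and
inter-block information recovered in the mixed-model analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PlotRecord", "TrialLayout", "generate_alpha_design", "concurrence_matrix"]


@dataclass(frozen=True)
class PlotRecord:
    """One plot: 1-based replicate, block (within replicate), plot (within block), treatment."""

    replicate: int
    block: int
    plot: int
    treatment: int


@dataclass
class TrialLayout:
    """An alpha-design layout mapping plots to (replicate, block, treatment).

    Indices are 1-based, matching agronomic field-book convention; arrays
    derived from a layout (see :meth:`arrays`) are 0-based.
    """

    n_treatments: int
    n_replicates: int
    blocks_per_replicate: int
    block_size: int
    assignment: list[PlotRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_plots(self) -> int:
        return self.n_replicates * self.blocks_per_replicate * self.block_size

    def validate(self) -> None:
        """Check all layout invariants; raise ValueError naming the broken rule."""
        t, r, b, k = (
            self.n_treatments,
            self.n_replicates,
            self.blocks_per_replicate,
            self.block_size,
        )
        if min(t, r, b, k) < 1:
            raise ValueError("design dimensions must be positive")
        if t != b * k:
            raise ValueError(f"design is not resolvable: t={t} != b*k={b * k}")
        if len(self.assignment) != self.n_plots:
            raise ValueError(
                f"expected {self.n_plots} plot records, got {len(self.assignment)}"
            )
        seen_rep: dict[int, list[int]] = {}
        seen_block: dict[tuple[int, int], list[int]] = {}
        for rec in self.assignment:
            if not (1 <= rec.replicate <= r and 1 <= rec.block <= b and 1 <= rec.plot <= k):
                raise ValueError(f"plot record out of range: {rec}")
            if not 1 <= rec.treatment <= t:
                raise ValueError(f"treatment label out of range: {rec}")
            seen_rep.setdefault(rec.replicate, []).append(rec.treatment)
            seen_block.setdefault((rec.replicate, rec.block), []).append(rec.treatment)
        for rep, treats in seen_rep.items():
            if sorted(treats) != list(range(1, t + 1)):
                raise ValueError(
                    f"replicate {rep} does not contain every treatment exactly once"
                )
        for (rep, blk), treats in seen_block.items():
            if len(treats) != k:
                raise ValueError(f"block ({rep},{blk}) has {len(treats)} plots, expected {k}")
            if len(set(treats)) != k:
                raise ValueError(
                    f"resolvability violated: treatment repeated in block ({rep},{blk})"
                )
        if len(seen_block) != r * b:
            raise ValueError("blocks within a replicate do not partition its plots")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return 0-based (replicate, block-global, treatment) index arrays, one row per plot.

        Plots are ordered by (replicate, block, plot).  The block index is
        global across replicates: ``rep * b + block``.
        """
        recs = sorted(self.assignment, key=lambda p: (p.replicate, p.block, p.plot))
        rep = np.array([p.replicate - 1 for p in recs], dtype=int)
        blk = np.array(
            [(p.replicate - 1) * self.blocks_per_replicate + (p.block - 1) for p in recs],
            dtype=int,
        )
        trt = np.array([p.treatment - 1 for p in recs], dtype=int)
        return rep, blk, trt


def _concurrence_from_blocks(blocks: np.ndarray, t: int) -> np.ndarray:
    """Concurrence matrix from an (n_blocks, k) array of 0-based treatments."""
    m = np.zeros((t, t), dtype=int)
    for block in blocks:
        idx = np.asarray(block)
        m[np.ix_(idx, idx)] += 1
    return m


def concurrence_matrix(layout: TrialLayout) -> np.ndarray:
    """t x t matrix counting, for each treatment pair, blocks containing both.

    The diagonal equals the number of blocks containing each treatment,
    i.e. the replication number ``r`` for a resolvable design.
    """
    t = layout.n_treatments
    blocks: dict[tuple[int, int], list[int]] = {}
    for rec in layout.assignment:
        blocks.setdefault((rec.replicate, rec.block), []).append(rec.treatment - 1)
    return _concurrence_from_blocks(
        np.array([sorted(v) for v in blocks.values()]), t
    )


def generate_alpha_design(
    t: int, r: int, k: int, seed: int, n_swaps: int = 2000
) -> TrialLayout:
    """Generate a randomised alpha design for ``t`` treatments, ``r`` replicates,
    blocks of ``k`` plots.

    Starts from an independent random partition of the treatments into blocks
    in every replicate, then applies a pairwise swap heuristic that minimises
    the spread of off-diagonal concurrence counts (a concurrence-balance
    criterion standing in for a D-optimality search).  Block order within
    replicate and plot order within block are randomised afterwards.

    Parameters
    ----------
    t, r, k
        Treatments, replicates (>= 2) and block size (2 <= k <= t,
        t divisible by k).
    seed
        Seed for the layout's own RNG; the same seed reproduces the same
        layout exactly.
    n_swaps
        Iteration budget of the swap heuristic.
    """
    if k > t:
        raise ValueError(f"block size k={k} exceeds number of treatments t={t}")
    if t % k != 0:
        raise ValueError(f"t={t} must be divisible by block size k={k}")
    if k < 2:
        raise ValueError("block size must be at least 2")
    if r < 2:
        raise ValueError("at least 2 replicates required")
    b = t // k
    rng = np.random.default_rng(seed)

    # blocks[rep] is a (b, k) array of 0-based treatments
    blocks = np.empty((r, b, k), dtype=int)
    for rep in range(r):
        blocks[rep] = rng.permutation(t).reshape(b, k)

    conc = _concurrence_from_blocks(blocks.reshape(r * b, k), t)

    def _pair_cost(m: np.ndarray) -> int:
        off = m[np.triu_indices(t, k=1)]
        return int(np.sum(off * off))

    cost = _pair_cost(conc)
    if b > 1:
        for _ in range(n_swaps):
            off = conc[np.triu_indices(t, k=1)]
            if off.max() - off.min() <= 1:
                break
            rep = rng.integers(r)
            b1, b2 = rng.choice(b, size=2, replace=False)
            p1, p2 = rng.integers(k), rng.integers(k)
            t1, t2 = blocks[rep, b1, p1], blocks[rep, b2, p2]
            if t1 == t2:
                continue
            # incremental concurrence update for swapping t1 <-> t2
            blk1 = blocks[rep, b1].copy()
            blk2 = blocks[rep, b2].copy()
            if t2 in blk1 or t1 in blk2:
                continue
            for blk, t_out, t_in in ((blk1, t1, t2), (blk2, t2, t1)):
                others = blk[blk != t_out]
                conc[t_out, others] -= 1
                conc[others, t_out] -= 1
                conc[t_in, others] += 1
                conc[others, t_in] += 1
            new_cost = _pair_cost(conc)
            if new_cost <= cost:
                blocks[rep, b1, p1], blocks[rep, b2, p2] = t2, t1
                cost = new_cost
            else:  # revert
                for blk, t_out, t_in in ((blk1, t1, t2), (blk2, t2, t1)):
                    others = blk[blk != t_out]
                    conc[t_out, others] += 1
                    conc[others, t_out] += 1
                    conc[t_in, others] -= 1
                    conc[others, t_in] -= 1

    # randomise block order within replicate and plot order within block
    assignment: list[PlotRecord] = []
    for rep in range(r):
        order = rng.permutation(b)
        for new_b, old_b in enumerate(order):
            plot_order = rng.permutation(k)
            for new_p, old_p in enumerate(plot_order):
                assignment.append(
                    PlotRecord(
                        replicate=rep + 1,
                        block=new_b + 1,
                        plot=new_p + 1,
                        treatment=int(blocks[rep, old_b, old_p]) + 1,
                    )
                )
    return TrialLayout(
        n_treatments=t,
        n_replicates=r,
        blocks_per_replicate=b,
        block_size=k,
        assignment=assignment,
    )
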