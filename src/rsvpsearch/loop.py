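"""The iterative closed loop: present -> decode -> propagate -> re-sequence.

Each iteration presents a sequence of images, obtains per-trial target
scores from a labeler (the real EEG decoding pipeline or the calibrated
synthetic stand-in), hardens and class-balances those labels, builds and
merges per-feature-space similarity graphs, and propagates the labels to
every image in the database.  Iterations run independently: only the
current iteration's EEG labels select the next sequence (the top-ranked
images by that iteration's propagation).  Evidence accumulates by
averaging the per-iteration propagated label vectors; after the final
iteration the database is ranked by the accumulated average and the top
images are retrieved.

Two comparison variants are provided: ``latest_only`` ranks by the last
iteration's propagation alone, and ``average_eeg_first`` averages the soft
EEG scores of all presented images across iterations, hardens them once,
and runs a single final propagation (presented images keep their averaged
soft scores in the final ranking).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._seeds import child_rng
from .decoding import harden
from .propagation import balance_labels, build_graph, merge_graphs, propagate
from .synthetic import ImageDatabase, simulate_labeler_scores

__all__ = [
    "LoopConfig",
    "LoopState",
    "initial_sequence",
    "next_sequence",
    "run_iteration",
    "run_loop",
    "final_labels",
    "make_synthetic_labeler",
    "rank_images",
]

#: labeler(image_ids, rng) -> per-trial soft target scores in [0, 1]
Labeler = Callable[[np.ndarray, np.random.Generator], np.ndarray]

VARIANTS = ("accumulate", "latest_only", "average_eeg_first")


@dataclass(frozen=True)
class LoopConfig:
    """Closed-loop run parameters.

    ``sequence_size`` is the number of images presented per iteration (two
    100-image RSVP sequences treated as one block); ``top_n_next`` images
    ranked as target seed the next iteration's sequence; the retrieval is
    the ``top_n_retrieved`` images of the final ranking.
    """

    n_iterations: int = 4
    sequence_size: int = 200
    top_n_next: int = 200
    top_n_retrieved: int = 200
    initial_target_fraction: float = 0.10
    variant: str = "accumulate"
    k_neighbors: int = 5
    hardening_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class LoopState:
    """Everything recorded across iterations of one closed-loop run."""

    node_ids: np.ndarray
    presented: list[np.ndarray] = field(default_factory=list)
    eeg_soft: list[np.ndarray] = field(default_factory=list)
    eeg_hard: list[np.ndarray] = field(default_factory=list)
    balanced: list[dict[int, int]] = field(default_factory=list)
    propagated: list[np.ndarray] = field(default_factory=list)
    presentation_count: np.ndarray = None

    def __post_init__(self) -> None:
        if self.presentation_count is None:
            self.presentation_count = np.zeros(len(self.node_ids), dtype=np.int64)

    @property
    def n_iterations_done(self) -> int:
        return len(self.propagated)

    def accumulated(self) -> np.ndarray:
        """Running mean of the per-iteration propagated label vectors."""
        if not self.propagated:
            raise ValueError("no completed iterations")
        return np.mean(np.stack(self.propagated), axis=0)


def rank_images(node_ids: np.ndarray, values: np.ndarray, top_n: int
                ) -> np.ndarray:
    """Top-n ids by descending value; ties broken by stable node-id order."""
    order = np.argsort(-np.asarray(values), kind="stable")
    return np.asarray(node_ids)[order[:top_n]]


def initial_sequence(db: ImageDatabase, target_class: int, cfg: LoopConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Uniformly sampled opening sequence with exact target prevalence."""
    from .synthetic import generate_presentation

    ids, _ = generate_presentation(db, target_class, cfg.sequence_size,
                                   cfg.initial_target_fraction, rng)
    return ids


def next_sequence(state: LoopState, cfg: LoopConfig) -> np.ndarray:
    """Sequence for the next iteration: current propagation's top images.

    Previously presented images may reappear -- a clamped hard-1 image
    outranks every node with a propagated label below 1.
    """
    if not state.propagated:
        raise ValueError("no completed iteration in state")
    return rank_images(state.node_ids, state.propagated[-1], cfg.top_n_next)


def run_iteration(db: ImageDatabase, sequence: np.ndarray, labeler: Labeler,
                  state: LoopState, cfg: LoopConfig,
                  rng: np.random.Generator) -> LoopState:
    """One closed-loop iteration; appends its results to ``state``."""
    it = state.n_iterations_done
    try:
        scores = np.asarray(labeler(sequence, rng), dtype=np.float64)
        hard = harden(scores, cfg.hardening_threshold)
        labels = {int(i): int(h) for i, h in zip(sequence, hard)}
        balanced = balance_labels(labels, rng)
        lab_ids = np.array(sorted(balanced))
        lab_vals = np.array([balanced[int(i)] for i in lab_ids])
        graphs = [
            build_graph(feat, db.ids, lab_ids, lab_vals, k=cfg.k_neighbors,
                        space=name)
            for name, feat in db.features.items()
        ]
        joint = merge_graphs(graphs)
        result = propagate(joint)
    except Exception as exc:
        raise RuntimeError(f"iteration {it} failed: {exc}") from exc

    state.presented.append(np.asarray(sequence).copy())
    state.eeg_soft.append(scores)
    state.eeg_hard.append(hard)
    state.balanced.append(balanced)
    state.propagated.append(result.values)
    idx = np.searchsorted(state.node_ids, sequence,
                          sorter=np.argsort(state.node_ids))
    np.add.at(state.presentation_count, np.argsort(state.node_ids)[idx], 1)
    return state


def final_labels(db: ImageDatabase, state: LoopState, cfg: LoopConfig,
                 variant: str | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Final per-image label vector for the requested ranking variant.

    * ``accumulate`` -- mean of the per-iteration propagated vectors.
    * ``latest_only`` -- the last iteration's propagation alone.
    * ``average_eeg_first`` -- average each presented image's soft EEG
      scores over its presentations, harden and balance once, run a single
      propagation, then restore the averaged soft scores on the presented
      images themselves.
    """
    variant = variant or cfg.variant
    if variant == "accumulate":
        return state.accumulated()
    if variant == "latest_only":
        if not state.propagated:
            raise ValueError("no completed iterations")
        return state.propagated[-1].copy()
    if variant != "average_eeg_first":
        raise ValueError(f"unknown variant {variant!r}")

    if rng is None:
        rng = child_rng(cfg.seed, "average-eeg-first")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for seq, scores in zip(state.presented, state.eeg_soft):
        for img, s in zip(seq, scores):
            sums[int(img)] = sums.get(int(img), 0.0) + float(s)
            counts[int(img)] = counts.get(int(img), 0) + 1
    avg_soft = {i: sums[i] / counts[i] for i in sums}
    hard = {i: int(v > cfg.hardening_threshold) for i, v in avg_soft.items()}
    balanced = balance_labels(hard, rng)
    lab_ids = np.array(sorted(balanced))
    lab_vals = np.array([balanced[int(i)] for i in lab_ids])
    graphs = [
        build_graph(feat, db.ids, lab_ids, lab_vals, k=cfg.k_neighbors,
                    space=name)
        for name, feat in db.features.items()
    ]
    result = propagate(merge_graphs(graphs))
    values = result.values.copy()
    # presented images keep their (averaged) soft EEG labels in this variant
    order = np.argsort(state.node_ids)
    for img, v in avg_soft.items():
        pos = order[np.searchsorted(state.node_ids, img, sorter=order)]
        values[pos] = v
    return values


def run_loop(db: ImageDatabase, target_class: int, labeler: Labeler,
             cfg: LoopConfig) -> tuple[LoopState, np.ndarray, np.ndarray]:
    """Run the full closed loop.

    Returns ``(state, final_label_vector, retrieved_ids)`` where the final
    vector follows ``cfg.variant`` and the retrieval is its
    ``cfg.top_n_retrieved`` top-ranked images.
    """
    rng = child_rng(cfg.seed, "closed-loop")
    state = LoopState(node_ids=db.ids.copy())
    sequence = initial_sequence(db, target_class, cfg, rng)
    for _ in range(cfg.n_iterations):
        run_iteration(db, sequence, labeler, state, cfg, rng)
        if state.n_iterations_done < cfg.n_iterations:
            sequence = next_sequence(state, cfg)
    values = final_labels(db, state, cfg, rng=rng)
    retrieved = rank_images(state.node_ids, values, cfg.top_n_retrieved)
    return state, values, retrieved


def make_synthetic_labeler(db: ImageDatabase, target_class: int,
                           target_auc: float) -> Labeler:
    """A labeler that stands in for the subject at a controlled quality.

    Scores come from the calibrated binormal model given the ground-truth
    class of each presented image, so loop-level behavior can be studied at
    a prescribed decoding AUC with no EEG simulation.
    """
    id_order = np.argsort(db.ids)

    def labeler(image_ids: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        pos = id_order[np.searchsorted(db.ids, image_ids, sorter=id_order)]
        is_target = (db.labels[pos] == target_class).astype(np.int64)
        return simulate_labeler_scores(is_target, target_auc, rng)

    return labeler
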