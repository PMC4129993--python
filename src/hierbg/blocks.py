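"""Per-subblock weighted multi-vector background model (coarse stage).

Each subblock carries an ordered set of K BTC feature vectors with weights
summing to one, maintained with mixture-style selective updates: the
highest-weight vectors whose cumulative weight first exceeds ``T`` represent
the background, the rest represent transient (object) appearances.  Matching
uses Euclidean distance in feature space against a threshold that is scaled
every frame by the similarity ``S`` between the incoming block and a running
background exemplar patch, so that a globally brighter or dimmer version of
the remembered background is still accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .btc import BlockFeature, block_similarity, btc_feature

BACKGROUND = "background"
OBJECT = "object"


@dataclass
class BlockModelConfig:
    """Tunables of the coarse stage.

    K
        Number of feature vectors kept per subblock.
    T
        Cumulative-weight threshold separating background from object
        vectors (0 < T < 1).
    T_D_base
        Base feature-distance threshold, in intensity units; the effective
        threshold each frame is ``T_D_base * (alpha + S)``.
    alpha
        Empirical constant of the adaptive threshold; sensible values lie
        in [0.7, 0.8].
    alpha_b
        Learning rate for feature and exemplar updates.
    alpha_w
        Learning rate for the weights, and the weight given to a newly
        created model vector.
    """

    K: int = 3
    T: float = 0.7
    T_D_base: float = 20.0
    alpha: float = 0.75
    alpha_b: float = 0.05
    alpha_w: float = 0.02

    def __post_init__(self):
        if not 0.0 < self.T < 1.0:
            raise ValueError("T must lie in (0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0.0 < self.alpha_b < 1.0 and 0.0 < self.alpha_w < 1.0):
            raise ValueError("learning rates must lie in (0, 1)")


@dataclass
class BlockModelEntry:
    """One (feature vector, weight) pair of a subblock model."""

    feature: np.ndarray  # 4-vector
    weight: float
    last_matched: int = -1  # frame index of most recent match, for tie-breaks
    placeholder: bool = False  # unfilled initialization slot; never matchable


@dataclass
class BlockModel:
    """State of one subblock: K weighted feature vectors plus an exemplar patch.

    Entries are kept sorted by weight (descending, ties broken by recency of
    match) so that the "first B_i vectors" of the background test are well
    defined.  The exemplar is a running average of the block's appearance
    over background-labeled frames and stands in for the remembered
    background when computing the similarity S.
    """

    entries: list[BlockModelEntry] = field(default_factory=list)
    exemplar: np.ndarray | None = None

    @property
    def weights(self) -> np.ndarray:
        return np.array([e.weight for e in self.entries])

    def _sort(self) -> None:
        self.entries.sort(key=lambda e: (-e.weight, -e.last_matched))


def init_model(
    first_feature: BlockFeature, first_block: np.ndarray, cfg: BlockModelConfig
) -> BlockModel:
    """Initialize a subblock model from the first frame.

    The first frame's feature gets all the weight; the remaining K - 1 slots
    are zero-weight placeholders that only become live when replaced by a
    newly observed appearance.
    """
    entries = [BlockModelEntry(first_feature.vector.copy(), 1.0, last_matched=0)]
    for _ in range(cfg.K - 1):
        entries.append(BlockModelEntry(np.zeros(4), 0.0, placeholder=True))
    return BlockModel(entries=entries, exemplar=np.asarray(first_block, dtype=float).copy())


def background_count(model: BlockModel, T: float) -> int:
    """Number B_i of highest-weight vectors representing the background.

    B_i is the smallest b >= 1 such that the cumulative weight of the top b
    entries strictly exceeds T.  Since the weights sum to one and T < 1,
    B_i <= K always.
    """
    cum = 0.0
    for b, entry in enumerate(model.entries, start=1):
        cum += entry.weight
        if cum > T:
            return b
    return len(model.entries)


def feature_distance(v: BlockFeature | np.ndarray, v_k: BlockFeature | np.ndarray) -> float:
    """Euclidean distance between two 4-component BTC feature vectors."""
    a = v.vector if isinstance(v, BlockFeature) else np.asarray(v, dtype=float)
    b = v_k.vector if isinstance(v_k, BlockFeature) else np.asarray(v_k, dtype=float)
    return float(np.linalg.norm(a - b))


def adaptive_threshold(t_d_base: float, alpha: float, similarity: float) -> float:
    """Effective distance threshold ``T_D_base * (alpha + S)``.

    Always computed fresh from the base value; the scaling is never
    compounded across frames.
    """
    return t_d_base * (alpha + similarity)


def classify_and_update(
    model: BlockModel, block: np.ndarray, cfg: BlockModelConfig, frame_index: int
) -> str:
    """Classify ``block`` as background/object and update ``model`` in place.

    The block's feature is matched (Euclidean distance below the
    similarity-adaptive threshold) against the stored vectors.  A match to
    one of the top B_i vectors is background; a match further down, or no
    match at all, is object.  On a match all weights receive the selective
    exponential update and the matched feature (plus the exemplar patch)
    additionally tracks the input when the label is background.  On no match
    the minimum-weight entry is replaced by the new appearance at weight
    ``alpha_w``.  Weights are renormalized to sum to one and entries
    re-sorted after every call.
    """
    if not model.entries or model.exemplar is None:
        raise ValueError("model is not initialized")
    block = np.asarray(block, dtype=float)
    v = btc_feature(block).vector
    s = block_similarity(block, model.exemplar)
    t_d_eff = adaptive_threshold(cfg.T_D_base, cfg.alpha, s)

    b_i = background_count(model, cfg.T)
    candidates = [
        (feature_distance(v, e.feature), -e.weight, idx)
        for idx, e in enumerate(model.entries)
        if not e.placeholder
    ]
    candidates = [c for c in candidates if c[0] < t_d_eff]

    if candidates:
        _, _, matched = min(candidates)
        label = BACKGROUND if matched < b_i else OBJECT
        for idx, e in enumerate(model.entries):
            m_k = 1.0 if idx == matched else 0.0
            e.weight = (1.0 - cfg.alpha_w) * e.weight + cfg.alpha_w * m_k
        entry = model.entries[matched]
        entry.last_matched = frame_index
        if label == BACKGROUND:
            entry.feature = (1.0 - cfg.alpha_b) * entry.feature + cfg.alpha_b * v
            model.exemplar = (1.0 - cfg.alpha_b) * model.exemplar + cfg.alpha_b * block
    else:
        # replace the weakest entry (stalest on ties) with the new appearance
        weakest = min(
            range(len(model.entries)),
            key=lambda i: (model.entries[i].weight, model.entries[i].last_matched),
        )
        model.entries[weakest] = BlockModelEntry(
            v.copy(), cfg.alpha_w, last_matched=frame_index
        )
        label = OBJECT

    total = sum(e.weight for e in model.entries)
    for e in model.entries:
        e.weight /= total
    model._sort()
    return label
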