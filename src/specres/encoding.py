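"""Pairwise binary encoding of sequence variation and specificity.

Every unordered pair of enzymes becomes one training instance. The
feature vector marks, per alignment column, whether the two sequences
differ there (1) or agree (0); the gap character counts as an ordinary
21st residue letter, so gap/gap scores 0 and gap/residue scores 1. One
extra Bernoulli(0.5) column — the control feature — provides a negative
control for the downstream importance analysis. The response is 1 when
the two enzymes sit in different specificity clusters and 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .io import EnzymePanel

CONTROL_COLUMN = "control"


def encode_pair(seq_a: str, seq_b: str) -> np.ndarray:
    """Binary difference vector between two aligned sequences.

    Symmetric in its arguments; position j is 1 iff the characters
    differ (case-insensitively).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}"
        )
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    return (a != b).astype(np.uint8)


@dataclass
class PairDataset:
    """One row per unordered enzyme pair.

    ``features`` has L+1 columns: alignment positions 1..L followed by
    the random control column; ``response`` is 1 for between-cluster
    pairs. Pairs are listed in lexicographic id order.
    """

    pairs: list[tuple[str, str]]
    features: np.ndarray  # (n_pairs, L+1) uint8
    response: np.ndarray  # (n_pairs,) uint8
    control_seed: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_positions(self) -> int:
        return self.features.shape[1] - 1

    def position_features(self) -> np.ndarray:
        """Feature block without the control column."""
        return self.features[:, :-1]

    def with_control(self, seed: int) -> "PairDataset":
        """Same dataset with the control column redrawn from ``seed``."""
        features = self.features.copy()
        features[:, -1] = _draw_control(self.n_pairs, seed)
        return PairDataset(
            pairs=self.pairs,
            features=features,
            response=self.response,
            control_seed=seed,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"pos{j}" for j in range(1, self.n_positions + 1)]
        df = pd.DataFrame(self.features, columns=cols + [CONTROL_COLUMN])
        df.insert(0, "enzyme_a", [a for a, _ in self.pairs])
        df.insert(1, "enzyme_b", [b for _, b in self.pairs])
        df["response"] = self.response
        return df


def _draw_control(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2, size=n, dtype=np.uint8)


def build_dataset(
    panel: EnzymePanel, clusters: ClusterAssignment, control_seed: int = 0
) -> PairDataset:
    """Assemble the pairwise training dataset from a panel and its clusters."""
    missing = sorted(set(panel.enzyme_ids) - set(clusters.labels.index))
    if missing:
        raise ValueError(f"enzymes without a cluster label: {missing}")

    order = sorted(range(panel.n_enzymes), key=lambda i: panel.enzyme_ids[i])
    seq = {eid: s for eid, s in zip(panel.enzyme_ids, panel.alignment)}

    pairs: list[tuple[str, str]] = []
    rows = []
    response = []
    for i, j in combinations(order, 2):
        a, b = panel.enzyme_ids[i], panel.enzyme_ids[j]
        pairs.append((a, b))
        rows.append(encode_pair(seq[a], seq[b]))
        response.append(int(clusters.label_of(a) != clusters.label_of(b)))

    features = np.empty((len(pairs), panel.length + 1), dtype=np.uint8)
    features[:, :-1] = np.vstack(rows)
    features[:, -1] = _draw_control(len(pairs), control_seed)
    return PairDataset(
        pairs=pairs,
        features=features,
        response=np.asarray(response, dtype=np.uint8),
        control_seed=control_seed,
    )
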