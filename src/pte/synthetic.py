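"""Planted-partition simulation of multi-sorter card-sort data.

The study's raw sort piles were never deposited, so the pipeline is
validated on synthetic datasets with known thematic structure: n
excerpts belong to K latent themes, and each of m sorters starts from
that planted partition and then corrupts it independently —

* with probability ``p_merge`` two random piles are merged (a sorter who
  perceives two themes as one),
* with probability ``p_split`` one random pile of >= 4 excerpts is split
  in two (a sorter who subdivides a theme),
* each excerpt is then moved to a uniformly random *other* pile with
  probability ``epsilon`` (item-level inconsistency — the mechanism that
  produces cross-cutting excerpts no theme retains).

Defaults mirror the study scale: 40 excerpts, 8 sorters, 4 themes.
Randomness comes from one root seed with an independent substream per
sorter, so adding a ninth sorter never perturbs the first eight.

Recovery of the planted themes is scored with the adjusted Rand index,
treating unassigned excerpts as singleton clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .communities import Clustering
from .errors import ConsistencyError, DesignError
from .sort_io import SortDataset


@dataclass(frozen=True)
class PlantedDesign:
    """Generative design for a synthetic card-sort study.

    ``theme_sizes`` must partition ``n``; None means a balanced split of
    n into K parts (remainders spread over the first themes).  All theme
    sizes of at least 2 are recommended — a size-1 theme can never be
    recovered as a group.
    """

    n: int = 40
    m: int = 8
    K: int = 4
    theme_sizes: tuple[int, ...] | None = None
    p_merge: float = 0.1
    p_split: float = 0.3
    epsilon: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        if self.n < 2 or self.m < 1:
            raise DesignError("need n >= 2 excerpts and m >= 1 sorters")
        if self.K < 2:
            raise DesignError(
                "K must be >= 2: with a single theme and the minimum-two-piles "
                "protocol there is no feasible sort"
            )
        for p, name in ((self.p_merge, "p_merge"), (self.p_split, "p_split"),
                        (self.epsilon, "epsilon")):
            if not 0.0 <= p <= 1.0:
                raise DesignError(f"{name} must lie in [0, 1], got {p}")
        if self.theme_sizes is not None:
            if len(self.theme_sizes) != self.K:
                raise DesignError("theme_sizes must have exactly K entries")
            if sum(self.theme_sizes) != self.n:
                raise DesignError(
                    f"theme_sizes must partition n={self.n}, "
                    f"got sum {sum(self.theme_sizes)}"
                )
            if any(s < 1 for s in self.theme_sizes):
                raise DesignError("theme sizes must be positive")

    def resolved_sizes(self) -> tuple[int, ...]:
        if self.theme_sizes is not None:
            return tuple(self.theme_sizes)
        base, extra = divmod(self.n, self.K)
        if base == 0:
            raise DesignError(f"cannot place {self.n} excerpts into {self.K} themes")
        return tuple(base + (1 if i < extra else 0) for i in range(self.K))


def apply_reassignment_noise(
    piles: list[list[str]], epsilon: float, rng: np.random.Generator
) -> tuple[list[list[str]], int]:
    """Move each excerpt to a uniformly random other pile with prob epsilon.

    Moves are decided against the pile layout as it stood on entry, in
    the lexical order of excerpt ids; emptied piles are dropped.  Returns
    the new piles and the number of excerpts moved (the generator's own
    Monte-Carlo diagnostic).
    """
    home = {e: i for i, pile in enumerate(piles) for e in pile}
    new_piles = [list(p) for p in piles]
    moved = 0
    if len(piles) >= 2:
        for e in sorted(home):
            if rng.random() < epsilon:
                src = home[e]
                choices = [i for i in range(len(piles)) if i != src]
                dst = choices[rng.integers(len(choices))]
                new_piles[src].remove(e)
                new_piles[dst].append(e)
                moved += 1
    return [p for p in new_piles if p], moved


def _one_sorter_piles(
    themes: list[list[str]], design: PlantedDesign, rng: np.random.Generator
) -> list[list[str]]:
    piles = [list(t) for t in themes]
    # at most one merge, never reducing the sorter below two piles
    if len(piles) >= 3 and rng.random() < design.p_merge:
        i, j = sorted(rng.choice(len(piles), size=2, replace=False))
        piles[i] = piles[i] + piles[j]
        del piles[j]
    # at most one split of a pile with at least 4 members
    if rng.random() < design.p_split:
        candidates = [i for i, p in enumerate(piles) if len(p) >= 4]
        if candidates:
            i = candidates[rng.integers(len(candidates))]
            pile = list(piles[i])
            rng.shuffle(pile)
            cut = int(rng.integers(2, len(pile) - 1))  # both halves >= 2
            piles[i] = pile[:cut]
            piles.append(pile[cut:])
    piles, _ = apply_reassignment_noise(piles, design.epsilon, rng)
    return piles


def simulate_sorts(
    design: PlantedDesign, seed: int | None = None
) -> tuple[SortDataset, dict[str, str]]:
    """Generate a sort dataset plus the ground-truth excerpt -> theme map.

    ``seed`` overrides ``design.seed``; one of the two must be given for
    reproducibility (None falls back to OS entropy).
    """
    root = seed if seed is not None else design.seed
    sizes = design.resolved_sizes()
    excerpts = [f"ID{i + 1}" for i in range(design.n)]
    themes: list[list[str]] = []
    truth: dict[str, str] = {}
    pos = 0
    for t, size in enumerate(sizes, start=1):
        block = excerpts[pos:pos + size]
        themes.append(block)
        for e in block:
            truth[e] = f"T{t}"
        pos += size
    records = []
    for s in range(design.m):
        rng = np.random.default_rng(
            np.random.SeedSequence([root, s]) if root is not None else None
        )
        piles = _one_sorter_piles(themes, design, rng)
        label_of = {
            e: f"Gp{i + 1}" for i, pile in enumerate(piles) for e in pile
        }
        pid = f"P{s + 1}"
        for e in excerpts:
            records.append((pid, e, label_of[e]))
    return SortDataset.from_records(records), truth


def write_truth_table(truth: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        sorted(truth.items()), columns=["excerpt_id", "theme_id"]
    ).to_csv(path, index=False)
    return path


def read_truth_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if not {"excerpt_id", "theme_id"} <= set(df.columns):
        raise ConsistencyError(f"{path}: expected columns excerpt_id, theme_id")
    return dict(zip(df["excerpt_id"], df["theme_id"]))


def recovery_score(clustering: Clustering, truth: dict[str, str]) -> float:
    """Adjusted Rand index between the clustering and the planted themes.

    Unassigned excerpts count as singleton clusters (each its own label),
    so leaving everything unassigned scores ~0, not 1.  Uses the standard
    permutation-model expectation correction; range [-1, 1].
    """
    have = clustering.excerpts()
    want = set(truth)
    if have != want:
        raise ConsistencyError(
            f"excerpt sets differ: clustering-only {sorted(have - want)}, "
            f"truth-only {sorted(want - have)}"
        )
    excerpts = sorted(want)
    true_labels = [truth[e] for e in excerpts]
    pred_labels = [
        f"G{clustering.groups[e]}" if e in clustering.groups else f"single:{e}"
        for e in excerpts
    ]
    return float(adjusted_rand_score(true_labels, pred_labels))
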