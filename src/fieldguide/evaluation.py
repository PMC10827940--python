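"""Retrieval metrics: per-class top-k accuracy and mean rank.

With exactly one relevant document per class, retrieval accuracy equals
classification accuracy.  Metrics are computed per class over that
class's images and then macro-averaged; ranks are 1-based, so a uniformly
random ranking has expected mean rank (K+1)/2 and expected top-k accuracy
100·k/K percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .retrieval import Ranking

__all__ = [
    "EvalReport",
    "evaluate",
    "random_guess_expectation",
    "random_guess_mean_rank",
]


@dataclass(frozen=True)
class EvalReport:
    top1: float                # percent
    top5: float                # percent
    mean_rank: float           # 1-based
    per_class: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    n_images: int = 0
    K: int = 0
    averaging: str = "macro"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "top1": self.top1, "top5": self.top5, "mean_rank": self.mean_rank,
            "n_images": self.n_images, "K": self.K, "averaging": self.averaging,
            "per_class": {c: {"top1": v[0], "top5": v[1], "mean_rank": v[2]}
                          for c, v in self.per_class.items()},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def to_tsv_row(self, method: str = "") -> str:
        return f"{method}\t{self.top1:.1f}\t{self.top5:.1f}\t{self.mean_rank:.1f}"


def evaluate(ranking: Ranking, truth: Mapping[str, str],
             averaging: str = "macro") -> EvalReport:
    """Score a ranking against image → class truth labels.

    Every ranked image must have a truth label and every truth class must
    be present in the ranking's class list.
    """
    if averaging not in ("macro", "micro"):
        raise ValueError("averaging must be 'macro' or 'micro'")
    K = len(ranking.class_ids)
    known = set(ranking.class_ids)
    by_class: dict[str, list[int]] = {}
    for img in ranking.image_ids:
        if img not in truth:
            raise ValueError(f"image {img!r} has no truth label")
        cls = truth[img]
        if cls not in known:
            raise ValueError(f"truth class {cls!r} absent from the corpus ranking")
        by_class.setdefault(cls, []).append(ranking.rank_of(img, cls))

    per_class: dict[str, tuple[float, float, float]] = {}
    for cls, ranks in sorted(by_class.items()):
        n = len(ranks)
        per_class[cls] = (
            100.0 * sum(r == 1 for r in ranks) / n,
            100.0 * sum(r <= 5 for r in ranks) / n,
            sum(ranks) / n,
        )

    if averaging == "macro":
        C = len(per_class)
        top1 = sum(v[0] for v in per_class.values()) / C
        top5 = sum(v[1] for v in per_class.values()) / C
        mr = sum(v[2] for v in per_class.values()) / C
    else:
        all_ranks = [r for ranks in by_class.values() for r in ranks]
        n = len(all_ranks)
        top1 = 100.0 * sum(r == 1 for r in all_ranks) / n
        top5 = 100.0 * sum(r <= 5 for r in all_ranks) / n
        mr = sum(all_ranks) / n

    return EvalReport(top1=top1, top5=top5, mean_rank=mr, per_class=per_class,
                      n_images=len(ranking.image_ids), K=K, averaging=averaging)


def random_guess_expectation(K: int, k: int = 1) -> float:
    """Expected top-k accuracy (percent) of a uniformly random ranking."""
    if not 1 <= k <= K:
        raise ValueError(f"need 1 <= k <= K, got k={k}, K={K}")
    return 100.0 * k / K


def random_guess_mean_rank(K: int) -> float:
    """Expected 1-based mean rank of the target under a random ranking."""
    if K < 1:
        raise ValueError("K must be positive")
    return (K + 1) / 2.0
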