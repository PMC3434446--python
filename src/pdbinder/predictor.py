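"""Binary binding-site predictions from propensity values.

Thresholding is inclusive (Pr >= cutoff): the default general cutoff of
0.143 means roughly 15% of a residue's matches must be against binding
pockets for it to be called positive.  An optional amino-acid-specific mode
applies one cutoff per residue type.  A spatial clustering filter then
discards predictions with no companion prediction within a radius (CA-CA,
inclusive, default 10 Å), reflecting that binding sites are contiguous
surface patches.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .propensity_engine import PropensityRecord
from .structure_model import STANDARD_AA, ResidueRecord

GENERAL_CUTOFF = 0.143
DEFAULT_CLUSTER_RADIUS = 10.0


@dataclass(frozen=True)
class ThresholdPolicy:
    """How propensity values are binarized and spatially filtered."""

    mode: str = "general"  # "general" | "residue_specific"
    general_cutoff: float = GENERAL_CUTOFF
    per_aa_cutoffs: dict[str, float] = field(default_factory=dict)
    clustering_radius: float = DEFAULT_CLUSTER_RADIUS  # 0 disables

    def cutoff_for(self, aa_type: str) -> float:
        if self.mode == "general":
            return self.general_cutoff
        if self.mode == "residue_specific":
            try:
                return self.per_aa_cutoffs[aa_type.upper()]
            except KeyError:
                raise ConfigurationError(
                    f"residue_specific mode: no cutoff for {aa_type!r}") from None
        raise ConfigurationError(f"unknown threshold mode {self.mode!r}")

    def validate(self) -> None:
        cutoffs = [self.general_cutoff, *self.per_aa_cutoffs.values()]
        if any(not (0.0 <= c <= 1.0) for c in cutoffs):
            raise ConfigurationError("cutoffs must lie in [0, 1]")
        if self.mode == "residue_specific":
            missing = set(STANDARD_AA) - set(self.per_aa_cutoffs)
            if missing:
                raise ConfigurationError(
                    f"residue_specific mode: missing cutoffs for {sorted(missing)}")


@dataclass
class Prediction:
    """Per-residue call before (raw) and after (final) the clustering filter."""

    residue: ResidueRecord
    pr: float
    raw_positive: bool
    final_positive: bool


def threshold_predict(records: list[PropensityRecord], policy: ThresholdPolicy
                      ) -> list[Prediction]:
    """raw_positive iff Pr >= the (general or per-type) cutoff.

    ``final_positive`` starts equal to ``raw_positive``; apply
    :func:`cluster_filter` to enforce the spatial companion rule.
    """
    policy.validate()
    preds = []
    for rec in records:
        pos = rec.pr >= policy.cutoff_for(rec.residue.aa_type)
        preds.append(Prediction(residue=rec.residue, pr=rec.pr,
                                raw_positive=pos, final_positive=pos))
    return preds


def cluster_filter(preds: list[Prediction], radius: float = DEFAULT_CLUSTER_RADIUS,
                   iterative: bool = False) -> list[Prediction]:
    """Discard raw positives without another raw positive within ``radius``.

    Companion distances are CA-to-CA and the radius is inclusive; radius 0
    disables the filter.  The default is a single pass over the raw
    positives; ``iterative=True`` re-applies the rule to the survivors until
    a fixed point is reached.
    """
    if radius <= 0:
        for p in preds:
            p.final_positive = p.raw_positive
        return preds
    active = [p.raw_positive for p in preds]
    cas = np.array([p.residue.ca if p.raw_positive else np.zeros(3) for p in preds])
    while True:
        keep = list(active)
        idx = [i for i, a in enumerate(active) if a]
        for i in idx:
            d = np.linalg.norm(cas[idx] - cas[i], axis=1)
            has_companion = np.any((d <= radius) & (np.array(idx) != i))
            keep[i] = bool(has_companion)
        if not iterative or keep == active:
            active = keep
            break
        active = keep
    for p, a in zip(preds, active):
        p.final_positive = bool(a)
    return preds


def predict(records: list[PropensityRecord], policy: ThresholdPolicy
            ) -> list[Prediction]:
    """Threshold then spatially filter in one call."""
    return cluster_filter(threshold_predict(records, policy), policy.clustering_radius)


def write_predictions_tsv(preds: list[Prediction], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chain", "seq_num", "icode", "aa_type", "pr",
                    "raw_positive", "final_positive"])
        for p in preds:
            r = p.residue
            w.writerow([r.chain_id, r.seq_num, r.insertion_code, r.aa_type,
                        f"{p.pr:.3f}", int(p.raw_positive), int(p.final_positive)])
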