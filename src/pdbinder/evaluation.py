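"""Performance metrics, ROC analysis and parameter-selection scans.

Two evaluation views are used: a *pooled* view, where the scored residues of
every chain are thrown together to draw a ROC curve and compute an AUC, and
a *macro* view, where sensitivity / specificity / PPV / MCC are computed per
chain and averaged with equal chain weight.  Model selection (the general
propensity cutoff, the 20 residue-specific cutoffs, and the clustering
radius) maximizes the macro-averaged MCC, which reflects the typical usage
of the predictor on one structure at a time.

Any metric with a zero denominator is defined as 0 so that macro averages
over chains with no predicted positives stay finite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import ConfigurationError, UndefinedMetricError
from .predictor import Prediction, ThresholdPolicy, cluster_filter
from .propensity_engine import PropensityRecord
from .structure_model import STANDARD_AA, ResidueRecord


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, PPV, MCC); zero denominators give 0."""

    def ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    sens = ratio(c.tp, c.tp + c.fn)
    spec = ratio(c.tn, c.tn + c.fp)
    ppv = ratio(c.tp, c.tp + c.fp)
    denom = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = (c.tp * c.tn - c.fp * c.fn) / denom if denom else 0.0
    return sens, spec, ppv, mcc


def confusion_from_calls(calls: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(calls & truth)), fp=int(np.sum(calls & ~truth)),
        tn=int(np.sum(~calls & ~truth)), fn=int(np.sum(~calls & truth)))


def pooled_roc_auc(records: list[tuple[float, bool]]
                   ) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) sweeping all distinct scores, and trapezoidal AUC.

    Tied scores are grouped (they enter or leave the positive set together).
    Raises :class:`UndefinedMetricError` if only one class is present.
    """
    scores = np.array([s for s, _ in records], dtype=float)
    labels = np.array([bool(l) for _, l in records])
    if labels.all() or not labels.any():
        raise UndefinedMetricError("AUC undefined: single-class input")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


# --------------------------------------------------------------------------
# Chain-level scoring containers
# --------------------------------------------------------------------------

@dataclass
class ChainScores:
    """Scores and truth labels for the residues of one chain."""

    scores: np.ndarray
    truth: np.ndarray
    aa_types: list[str] | None = None
    residues: list[ResidueRecord] | None = None
    chain_id: str = ""

    @classmethod
    def from_records(cls, records: list[PropensityRecord], chain_id: str = ""
                     ) -> "ChainScores":
        """Truth is taken from each residue's ``is_binding`` flag."""
        return cls(
            scores=np.array([r.pr for r in records], dtype=float),
            truth=np.array([bool(r.residue.is_binding) for r in records]),
            aa_types=[r.residue.aa_type for r in records],
            residues=[r.residue for r in records],
            chain_id=chain_id or (records[0].residue.chain_id if records else ""),
        )


def _macro_mcc(chains: list[ChainScores], cutoffs_fn) -> float:
    vals = []
    for ch in chains:
        calls = ch.scores >= cutoffs_fn(ch)
        *_, mcc = confusion_metrics(confusion_from_calls(calls, ch.truth))
        vals.append(mcc)
    return float(np.mean(vals)) if vals else 0.0


def optimize_threshold(chains: list[ChainScores],
                       grid: np.ndarray | list[float] | None = None,
                       per_aa: bool = False,
                       clustering_radius: float = 0.0,
                       ) -> tuple[ThresholdPolicy, float, list[tuple[float, float]]]:
    """Cutoff(s) maximizing the macro-averaged MCC over chains.

    The default grid is every distinct observed score plus 0, which finds
    the exact argmax without arbitrary discretization.  Ties are broken by
    the smallest cutoff.  In ``per_aa`` mode the scan is repeated
    independently for each amino-acid type with the other types held at the
    general cutoff.  Returns (policy, best macro-MCC, the (cutoff, MCC)
    table of the general scan).

    For leave-one-out training each chain's scores must already have been
    computed with its own homology cluster excluded from the library.
    """
    if grid is None:
        observed = np.unique(np.concatenate([ch.scores for ch in chains]))
        grid = np.unique(np.concatenate([[0.0], observed]))
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ConfigurationError("empty cutoff grid")

    table = [(float(c), _macro_mcc(chains, lambda ch, c=c: c)) for c in np.sort(grid)]
    best_cut, best_mcc = max(table, key=lambda t: (t[1], -t[0]))

    if not per_aa:
        policy = ThresholdPolicy(mode="general", general_cutoff=best_cut,
                                 clustering_radius=clustering_radius)
        return policy, best_mcc, table

    per_cut: dict[str, float] = {}
    for aa in STANDARD_AA:
        best_aa = (best_mcc, best_cut)
        for c in np.sort(grid):
            def cutoffs(ch: ChainScores, c=float(c), aa=aa) -> np.ndarray:
                assert ch.aa_types is not None
                return np.array([c if t == aa else best_cut for t in ch.aa_types])
            mcc = _macro_mcc(chains, cutoffs)
            if mcc > best_aa[0] or (mcc == best_aa[0] and c < best_aa[1]):
                best_aa = (mcc, float(c))
        per_cut[aa] = best_aa[1]

    def final_cutoffs(ch: ChainScores) -> np.ndarray:
        assert ch.aa_types is not None
        return np.array([per_cut[t] for t in ch.aa_types])

    final_mcc = _macro_mcc(chains, final_cutoffs)
    policy = ThresholdPolicy(mode="residue_specific", general_cutoff=best_cut,
                             per_aa_cutoffs=per_cut,
                             clustering_radius=clustering_radius)
    return policy, final_mcc, table


def scan_cluster_radius(chain_preds: list[tuple[list[Prediction], np.ndarray]],
                        radii: np.ndarray | list[float] | None = None,
                        ) -> tuple[float, list[tuple[float, float]]]:
    """Macro-MCC of the clustering filter at each radius; argmax returned.

    ``chain_preds`` pairs each chain's raw predictions with its truth
    labels.  The default radius grid is 1.0-20.0 Å in 1 Å steps; ties are
    broken by the smallest radius.
    """
    if radii is None:
        radii = np.arange(1.0, 20.0 + 1e-9, 1.0)
    table = []
    for radius in radii:
        vals = []
        for preds, truth in chain_preds:
            filtered = cluster_filter(preds, float(radius))
            calls = np.array([p.final_positive for p in filtered])
            *_, mcc = confusion_metrics(confusion_from_calls(calls, truth))
            vals.append(mcc)
        table.append((float(radius), float(np.mean(vals)) if vals else 0.0))
    best_radius, _ = max(table, key=lambda t: (t[1], -t[0]))
    return best_radius, table


# --------------------------------------------------------------------------
# Binding-site geometry
# --------------------------------------------------------------------------

def binding_site_radius(pocket: list[ResidueRecord]) -> float:
    """Radius of a pocket: the maximum CA distance from the CA centroid."""
    if not pocket:
        raise ValueError("empty pocket")
    cas = np.array([r.ca for r in pocket])
    centroid = cas.mean(axis=0)
    return float(np.max(np.linalg.norm(cas - centroid, axis=1)))


def site_radius_stats(pockets: list[list[ResidueRecord]], confidence: float = 0.99
                      ) -> tuple[float, float]:
    """Cohort mean pocket radius with a normal-theory (t) confidence
    half-width."""
    radii = np.array([binding_site_radius(p) for p in pockets])
    mean = float(radii.mean())
    if len(radii) < 2:
        return mean, 0.0
    sem = float(radii.std(ddof=1) / math.sqrt(len(radii)))
    half = float(stats.t.ppf(0.5 + confidence / 2, df=len(radii) - 1) * sem)
    return mean, half


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

@dataclass
class EvalReport:
    per_chain: list[dict] = field(default_factory=list)
    macro: dict = field(default_factory=dict)
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"per_chain": self.per_chain, "macro": self.macro,
                   "auc": self.auc, "roc_points": self.roc_points}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate_chains(chains: list[ChainScores], policy: ThresholdPolicy) -> EvalReport:
    """Apply the policy (threshold + clustering) per chain and report both
    macro-averaged metrics and the pooled ROC/AUC of the raw scores."""
    report = EvalReport()
    metric_rows = []
    for ch in chains:
        cutoffs = np.array([policy.cutoff_for(t) for t in (ch.aa_types or [])]) \
            if ch.aa_types else np.full(len(ch.scores), policy.general_cutoff)
        calls = ch.scores >= cutoffs
        if policy.clustering_radius > 0 and ch.residues is not None:
            preds = [Prediction(residue=r, pr=s, raw_positive=bool(c), final_positive=bool(c))
                     for r, s, c in zip(ch.residues, ch.scores, calls)]
            cluster_filter(preds, policy.clustering_radius)
            calls = np.array([p.final_positive for p in preds])
        cc = confusion_from_calls(calls, ch.truth)
        sens, spec, ppv, mcc = confusion_metrics(cc)
        row = {"chain": ch.chain_id, "tp": cc.tp, "fp": cc.fp, "tn": cc.tn,
               "fn": cc.fn, "sensitivity": sens, "specificity": spec,
               "ppv": ppv, "mcc": mcc}
        report.per_chain.append(row)
        metric_rows.append((sens, spec, ppv, mcc))
    if metric_rows:
        arr = np.array(metric_rows)
        report.macro = {k: float(v) for k, v in zip(
            ("sensitivity", "specificity", "ppv", "mcc"), arr.mean(axis=0))}
    pooled = [(float(s), bool(t)) for ch in chains for s, t in zip(ch.scores, ch.truth)]
    try:
        report.roc_points, report.auc = pooled_roc_auc(pooled)
    except UndefinedMetricError:
        report.auc = None
    return report


# --------------------------------------------------------------------------
# Holo -> apo truth transfer
# --------------------------------------------------------------------------

def transfer_binding_labels(holo: list[ResidueRecord], apo: list[ResidueRecord]
                            ) -> list[ResidueRecord]:
    """Copy binding-truth labels from a holo chain onto its apo counterpart.

    Residues are matched by author numbering ``(seq_num, icode)``; if the
    amino-acid types disagree anywhere, a global sequence alignment is used
    as a fallback and 100% identity over the aligned positions is required
    (only identical-sequence apo/holo pairs are meaningful for residue-level
    truth transfer).
    """
    holo_by_num = {(r.seq_num, r.insertion_code): r for r in holo}
    consistent = all(
        holo_by_num[(a.seq_num, a.insertion_code)].aa_type == a.aa_type
        for a in apo if (a.seq_num, a.insertion_code) in holo_by_num)
    if consistent and any((a.seq_num, a.insertion_code) in holo_by_num for a in apo):
        for a in apo:
            h = holo_by_num.get((a.seq_num, a.insertion_code))
            a.is_binding = bool(h.is_binding) if h is not None else False
        return apo

    from Bio import Align
    from Bio.PDB.Polypeptide import protein_letters_3to1
    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=-10, open_gap_score=-5,
                                    extend_gap_score=-0.5)
    s_holo = "".join(protein_letters_3to1.get(r.aa_type, "X") for r in holo)
    s_apo = "".join(protein_letters_3to1.get(r.aa_type, "X") for r in apo)
    aln = aligner.align(s_holo, s_apo)[0]
    for a in apo:
        a.is_binding = False
    for (h0, h1), (a0, a1) in zip(*aln.aligned):
        for hi, ai in zip(range(h0, h1), range(a0, a1)):
            if s_holo[hi] != s_apo[ai]:
                raise ConfigurationError(
                    "holo/apo sequences are not 100% identical over the alignment")
            apo[ai].is_binding = bool(holo[hi].is_binding)
    return apo
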