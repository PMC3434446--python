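"""From match lists to per-residue propensity values.

Each accepted match between a query triplet and a library triplet counts
once for each of the three query residues involved, towards ``Tot_bind``
if the library triplet comes from the binding library and ``Tot_other``
otherwise.  The propensity

    Pr = Tot_bind / (Tot_bind + Tot_other)

ranges from 0 (never matched a known binding pocket) to 1 (only ever
matched binding pockets); residues with no matches at all get Pr = 0 and
can never be predicted positive.

The module also provides the composition-only baseline: a potential over
sorted amino-acid compositions (AVV = VAV = VVA), ignoring geometry, used
to quantify how much of the signal comes from triplet geometry rather than
from binding-site amino-acid preferences.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .errors import PDBinderError
from .library_builder import ResidueLibrary
from .motif_matcher import (Match, MotifTriplet, ParamConfig,
                            enumerate_triplets, library_triplets)
from .structure_model import ResidueRecord


def propensity_value(tot_bind: int, tot_other: int) -> float:
    """Pr = Tot_bind / (Tot_bind + Tot_other); 0 when both counts are 0."""
    total = tot_bind + tot_other
    return tot_bind / total if total > 0 else 0.0


@dataclass
class PropensityRecord:
    """Per-residue match counts and propensity."""

    residue: ResidueRecord
    tot_bind: int = 0
    tot_other: int = 0

    @property
    def pr(self) -> float:
        return propensity_value(self.tot_bind, self.tot_other)


def triplet_label(lib_triplet: MotifTriplet) -> str:
    """``"binding"`` or ``"non_binding"``; mixed triplets are a library bug."""
    flags = {r.is_binding for r in lib_triplet.residues}
    if flags == {True}:
        return "binding"
    if flags == {False}:
        return "non_binding"
    raise PDBinderError(
        f"mixed binding/non-binding triplet at scoring time: {lib_triplet.keys}")


def accumulate_propensity(matches: list[Match], query: list[ResidueRecord]
                          ) -> list[PropensityRecord]:
    """One record per query residue; every match increments all three of its
    query residues by one in the count matching its library-triplet label."""
    records = {res.key: PropensityRecord(residue=res) for res in query}
    for m in matches:
        binding = triplet_label(m.library_triplet) == "binding"
        for res in m.query_triplet.residues:
            rec = records.get(res.key)
            if rec is None:
                continue
            if binding:
                rec.tot_bind += 1
            else:
                rec.tot_other += 1
    return list(records.values())


def write_propensity_tsv(records: list[PropensityRecord], path: str | Path) -> None:
    """Per-residue table; Pr is printed to three decimals."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chain", "seq_num", "icode", "aa_type",
                    "tot_bind", "tot_other", "pr"])
        for rec in records:
            r = rec.residue
            w.writerow([r.chain_id, r.seq_num, r.insertion_code, r.aa_type,
                        rec.tot_bind, rec.tot_other, f"{rec.pr:.3f}"])


# --------------------------------------------------------------------------
# Composition-only baseline
# --------------------------------------------------------------------------

@dataclass
class CompositionPotential:
    """Average propensity per sorted amino-acid composition.

    ``values[comp]`` is the fraction of the library triplets of that
    composition that lie in binding pockets, pooling every permutation and
    geometry.  Compositions never observed are absent (and score 0).
    """

    values: dict[tuple[str, str, str], float]
    counts: dict[tuple[str, str, str], tuple[int, int]]  # (bind, total)

    def value(self, comp: tuple[str, str, str]) -> float:
        return self.values.get(comp, 0.0)


def composition_potential_build(lib: ResidueLibrary, cfg: ParamConfig = ParamConfig()
                                ) -> CompositionPotential:
    bind: dict[tuple[str, str, str], int] = {}
    total: dict[tuple[str, str, str], int] = {}
    for t, _chain, _cluster, is_binding in library_triplets(lib, cfg):
        key = t.aa_key
        total[key] = total.get(key, 0) + 1
        if is_binding:
            bind[key] = bind.get(key, 0) + 1
    values = {k: bind.get(k, 0) / n for k, n in total.items()}
    counts = {k: (bind.get(k, 0), n) for k, n in total.items()}
    return CompositionPotential(values=values, counts=counts)


def composition_score(query: list[ResidueRecord], pot: CompositionPotential,
                      cfg: ParamConfig = ParamConfig()) -> dict[tuple, float]:
    """Per-residue baseline score: the mean potential of the enumerated query
    triplets containing the residue (0 for residues in no triplet)."""
    sums: dict[tuple, float] = {res.key: 0.0 for res in query}
    counts: dict[tuple, int] = {res.key: 0 for res in query}
    for t in enumerate_triplets(query, cfg):
        v = pot.value(t.aa_key)
        for res in t.residues:
            sums[res.key] += v
            counts[res.key] += 1
    return {k: (sums[k] / counts[k] if counts[k] else 0.0) for k in sums}
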