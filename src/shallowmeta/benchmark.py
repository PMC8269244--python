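"""Profiler evaluation: DExA index, confusion rates, depth titration.

The **DExA index** (Deviation from Expected Abundance) summarizes the
disagreement between an observed and an expected relative-abundance
profile: half the L1 distance over the union of species,

    DExA = ( sum_i |obs_i - exp_i| ) / 2   [percent]

so identical profiles score 0% and profiles with disjoint species sets
score 100%.  The halving reconciles "sum of absolute deviations" with a
0-100% scale: a species' mass that goes missing is otherwise counted twice
(once as a shortfall, once as the surplus that replaced it).

**Confusion rates** follow the database-ablation design: reads simulated
from species *kept* in the database should land on their true species
(TP; anything else, including unclassified, counts against the TP rate),
while reads from *ablated* species should be rejected or pushed above the
species rank (TN; a confident call to a concrete species is the failure
mode, labelled FN here following the ablation convention — an alternative
textbook labelling is also emitted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import pandas as pd

from .readprofiler import Profile, Read, ReadClassification, aggregate_profile, subsample
from .simdata import TruthManifest


class BenchmarkError(ValueError):
    pass


# ---------------------------------------------------------------------------
# DExA


def dexa(
    observed: Mapping[str, float],
    expected: Mapping[str, float],
    observed_unclassified: float = 0.0,
    tol: float = 1e-6,
) -> float:
    """Deviation-from-Expected-Abundance between two percent profiles.

    Both profiles must sum to 100 (the observed one after adding
    ``observed_unclassified`` mass, for callers that do not renormalize
    over classified reads).  Missing species count as 0 on the other side.
    """
    for name, prof, extra in (
        ("observed", observed, observed_unclassified),
        ("expected", expected, 0.0),
    ):
        total = sum(prof.values()) + extra
        if abs(total - 100.0) > max(tol, 1e-6 * 100.0):
            raise BenchmarkError(f"{name} profile sums to {total}, not 100")
    keys = set(observed) | set(expected)
    l1 = sum(abs(observed.get(k, 0.0) - expected.get(k, 0.0)) for k in keys)
    l1 += observed_unclassified  # unclassified mass matches nothing expected
    return l1 / 2.0


def dexa_from_profile(profile: Profile, expected: Mapping[str, float]) -> float:
    """DExA of a read profile's relative abundances against a truth profile."""
    return dexa(profile.relative, expected)


# ---------------------------------------------------------------------------
# Confusion under database ablation


@dataclass(frozen=True)
class ConfusionCounts:
    """Ablation-convention confusion counts and rates.

    ``tp + fp`` equals the reads drawn from in-database species and
    ``tn + fn`` the reads drawn from ablated species.  ``textbook`` holds
    the conventional relabelling in which a confident wrong call on an
    ablated-species read is the false *positive*.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tp_rate(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def fp_rate(self) -> float:
        return self.fp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def tn_rate(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else 0.0

    @property
    def fn_rate(self) -> float:
        return self.fn / (self.tn + self.fn) if (self.tn + self.fn) else 0.0

    @property
    def textbook(self) -> dict[str, int]:
        return {"tp": self.tp, "fn": self.fp, "tn": self.tn, "fp": self.fn}


def confusion(
    classifications: Sequence[ReadClassification],
    manifest: TruthManifest,
    in_db_species: set[str],
) -> ConfusionCounts:
    """Score per-read calls against truth under database ablation.

    * read from an in-db species, species-level call to its true species → TP;
      any other outcome → FP;
    * read from an ablated species left unclassified or assigned above the
      species rank → TN; a species-level call to a concrete species → FN.
    """
    truth = dict(zip(manifest.rows["read_id"], manifest.rows["species"]))
    tp = fp = tn = fn = 0
    for c in classifications:
        if c.read_id not in truth:
            raise BenchmarkError(f"read {c.read_id!r} absent from truth manifest")
        true_species = truth[c.read_id]
        concrete_species = c.assigned_rank == "species" and c.species_label is not None
        if true_species in in_db_species:
            if concrete_species and c.species_label == true_species:
                tp += 1
            else:
                fp += 1
        else:
            if concrete_species:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def confusion_to_frame(counts: ConfusionCounts) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
                "tp_rate": counts.tp_rate, "fp_rate": counts.fp_rate,
                "tn_rate": counts.tn_rate, "fn_rate": counts.fn_rate,
            }
        ]
    )


# ---------------------------------------------------------------------------
# Depth titration


def depth_titration(
    reads: Sequence[Read],
    expected: Mapping[str, float],
    depths: Sequence[int],
    classify: Callable[[Sequence[Read]], Sequence[ReadClassification]],
    seed: int = 0,
    tree=None,
) -> pd.DataFrame:
    """DExA as a function of sequencing depth.

    For each depth a seeded subsample is classified and profiled and its
    relative abundances are compared with the expected profile.  Depths
    exceeding the available read count use all reads.
    """
    records = []
    for depth in depths:
        sample = subsample(reads, n=depth, seed=seed)
        classifications = classify(sample)
        profile = aggregate_profile(classifications, tree)
        value = dexa(profile.relative, expected) if profile.counts else 100.0
        records.append(
            {
                "depth": min(depth, len(reads)),
                "dexa_pct": value,
                "classified": profile.total_classified,
                "unclassified": profile.unclassified_count,
            }
        )
    return pd.DataFrame(records, columns=["depth", "dexa_pct", "classified", "unclassified"])
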