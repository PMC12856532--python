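"""Tissue-overlap partitioning and hypergeometric over-representation.

Differential calls from the two tissues are partitioned per direction into
liver-unique / common / muscle-unique sets (the Venn diagram logic), and
each partition is tested against annotation sets with the one-sided
hypergeometric upper tail.  A set is flagged significant when its BH-adjusted
p is <= 0.05 AND it is enriched for at least 2 features.  The same machinery
drives the drug-signature repurposing screen over gene and protein
partitions, reporting the top 10 signatures per partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnnotationCollection, ValidationError
from .differential import bh_adjust

log = logging.getLogger("duomics")

PARTITIONS = ("liver_unique", "common", "muscle_unique")


@dataclass
class OverlapPartition:
    """Per-direction Venn partition of the two tissues' called features."""

    direction: str
    liver_unique: frozenset
    common: frozenset
    muscle_unique: frozenset
    universe: frozenset

    def counts(self) -> dict:
        return dict(direction=self.direction,
                    liver_unique=len(self.liver_unique),
                    common=len(self.common),
                    muscle_unique=len(self.muscle_unique))

    def get(self, name: str) -> frozenset:
        return getattr(self, name)


def partition(liver_calls, muscle_calls, universe, direction: str) -> OverlapPartition:
    """Venn partition of one direction's calls.  Tissues must share the
    layer's universe of surviving features."""
    liver = frozenset(liver_calls)
    muscle = frozenset(muscle_calls)
    universe = frozenset(universe)
    if not liver <= universe or not muscle <= universe:
        raise ValidationError("calls outside the shared universe")
    return OverlapPartition(
        direction=direction,
        liver_unique=liver - muscle,
        common=liver & muscle,
        muscle_unique=muscle - liver,
        universe=universe,
    )


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValidationError(f"inconsistent hypergeometric arguments k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom(N, K, n).sf(k - 1))


def run_ora(partitions: dict, collection: AnnotationCollection, mapping: pd.Series,
            universe_rule: str = "mapped", alpha: float = 0.05, min_hits: int = 2) -> pd.DataFrame:
    """Over-representation of every collection set in every partition.

    ``mapping`` maps feature ids to the collection's identifier space (gene
    symbols, class labels, ...); unmapped features are excluded from the
    universe under the default ``mapped`` rule, retained (as unmatchable)
    under ``all``.  BH adjustment is within collection x partition; the
    significant flag requires adjusted p <= alpha AND >= min_hits hits.
    """
    mapping = mapping.dropna()
    rows = []
    for part_id, features in partitions.items():
        direction = part_id.rsplit("_", 1)[-1]
        universe_feats = features["universe"]
        mapped_universe = {mapping[f] for f in universe_feats if f in mapping.index}
        if universe_rule == "mapped":
            member_space = collection.member_universe()
            mapped_universe = {m for m in mapped_universe if m in member_space}
        if not mapped_universe:
            raise ValidationError(f"empty mapped universe for partition {part_id}")
        selected = {mapping[f] for f in features["selected"] if f in mapping.index}
        selected &= mapped_universe
        N = len(mapped_universe)
        n = len(selected)
        part_rows = []
        for set_name in sorted(collection.sets):
            members = collection.sets[set_name] & mapped_universe
            K = len(members)
            if K == 0:
                continue
            k = len(selected & members)
            p = hypergeom_p(k, K, n, N)
            pct = 100.0 * k / K
            part_rows.append(dict(partition=part_id, direction=direction,
                                  collection=collection.name, set_name=set_name,
                                  universe_N=N, set_K=K, selected_n=n, hits_k=k,
                                  pct_of_set=pct, p_value=p))
        if part_rows:
            sub = pd.DataFrame(part_rows)
            sub["adj_p"] = bh_adjust(sub["p_value"].to_numpy())
            sub["significant"] = (sub["adj_p"] <= alpha) & (sub["hits_k"] >= min_hits)
            rows.append(sub)
    if not rows:
        return pd.DataFrame(columns=["partition", "direction", "collection", "set_name",
                                     "universe_N", "set_K", "selected_n", "hits_k",
                                     "pct_of_set", "p_value", "adj_p", "significant"])
    return pd.concat(rows, ignore_index=True)


def partitions_for_ora(overlaps: dict) -> dict:
    """Flatten {direction: OverlapPartition} into named selections for ORA."""
    out = {}
    for direction, part in overlaps.items():
        for name in PARTITIONS:
            out[f"{name}_{direction}"] = dict(selected=part.get(name),
                                              universe=part.universe)
    return out


def drug_repurposing(gene_overlaps: dict, protein_overlaps: dict,
                     drug_collection: AnnotationCollection,
                     gene_mapping: pd.Series, protein_mapping: pd.Series,
                     alpha: float = 0.05, min_hits: int = 2, top_k: int = 10) -> pd.DataFrame:
    """Drug-signature ORA over gene (G) and protein (P) partitions.

    Each compound's target set is tested against every common/unique
    partition in both input layers; per partition the top ``top_k``
    signatures are ranked by adjusted p with deterministic tie-breaking
    (smaller p, then more hits, then name).
    """
    frames = []
    for input_layer, overlaps, mapping in (("G", gene_overlaps, gene_mapping),
                                           ("P", protein_overlaps, protein_mapping)):
        res = run_ora(partitions_for_ora(overlaps), drug_collection, mapping,
                      alpha=alpha, min_hits=min_hits)
        res["input_layer"] = input_layer
        frames.append(res)
    allres = pd.concat(frames, ignore_index=True)
    ranked = []
    for (part_id, layer_tag), sub in allres.groupby(["partition", "input_layer"]):
        sub = sub.sort_values(["adj_p", "p_value", "hits_k", "set_name"],
                              ascending=[True, True, False, True], kind="stable")
        sub = sub.head(top_k).copy()
        sub["rank"] = np.arange(1, len(sub) + 1)
        ranked.append(sub)
    if not ranked:
        return allres
    return pd.concat(ranked, ignore_index=True)


def build_class_collection(name: str, labels: pd.Series) -> AnnotationCollection:
    """Annotation collection whose sets are the levels of a feature label
    (lipid main class, metabolite super-pathway, ...)."""
    sets = {}
    for label, members in labels.dropna().groupby(labels.dropna()).groups.items():
        sets[str(label)] = frozenset(members)
    return AnnotationCollection(name, sets)
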