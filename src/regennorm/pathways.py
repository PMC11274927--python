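"""Multi-ome pathway-set intersection.

Each ome (proteome, metabolome, lipidome) contributes the union of
pathway annotations over its significant entities; ome combinations are
intersected to find pathways implicated across molecular layers.  The
cardinality is anti-monotone in the combination: adding an ome can only
shrink the shared set, which is why three-ome intersections pinpoint the
few pathways with multi-nodal involvement.

Annotation maps are offline files (KEGG-Mapper-style presence/absence
listings); no live database queries.
"""

from __future__ import annotations

import itertools
import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import pandas as pd

from .types import ConfigurationError, Ome, PathwayAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OmeIntersection:
    """Pathways common to every ome in a combination (>= 2 omes)."""

    combination: tuple[Ome, ...]
    pathways: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.pathways)


def pathways_for_ome(
    significant_entities: Iterable[str],
    annotations: Iterable[PathwayAnnotation],
    ome: Ome | str,
) -> set[str]:
    """Union of pathway ids over an ome's significant entities.

    Entities without an annotation are counted and logged, not errors:
    un-mapped identifiers are routine in pathway mapping.
    """
    ome = Ome(ome)
    entities = set(significant_entities)
    by_entity = {a.entity_id: a for a in annotations if a.ome == ome}
    hit: set[str] = set()
    unannotated = 0
    for entity in entities:
        ann = by_entity.get(entity)
        if ann is None:
            unannotated += 1
            continue
        hit |= ann.pathway_ids
    if unannotated:
        logger.info(
            "%s: %d of %d significant entities had no pathway annotation",
            ome.value, unannotated, len(entities),
        )
    return hit


def intersect_omes(
    per_ome_sets: Mapping[Ome | str, set[str]],
    combination: Iterable[Ome | str],
) -> OmeIntersection:
    """Intersect the pathway sets of an ome combination (>= 2 omes)."""
    per_ome = {Ome(k): set(v) for k, v in per_ome_sets.items()}
    combo = tuple(Ome(o) for o in combination)
    if len(combo) < 2 or len(set(combo)) != len(combo):
        raise ConfigurationError(
            f"combination needs >= 2 distinct omes, got {[o.value for o in combo]}"
        )
    for o in combo:
        if o not in per_ome:
            raise ConfigurationError(f"no pathway set for ome {o.value!r}")
    shared = set.intersection(*(per_ome[o] for o in combo))
    return OmeIntersection(combination=combo, pathways=frozenset(shared))


def all_intersections(per_ome_sets: Mapping[Ome | str, set[str]]) -> list[OmeIntersection]:
    """Every >= 2-ome combination of the provided omes, largest last."""
    omes = sorted((Ome(k) for k in per_ome_sets), key=lambda o: o.value)
    out = []
    for r in range(2, len(omes) + 1):
        for combo in itertools.combinations(omes, r):
            out.append(intersect_omes(per_ome_sets, combo))
    return out


def intersections_frame(intersections: Iterable[OmeIntersection]) -> pd.DataFrame:
    """Tabulate intersections with deterministic (lexicographic) ordering."""
    rows = [
        {
            "combination": "+".join(o.value for o in ix.combination),
            "n_pathways": ix.count,
            "pathways": ";".join(sorted(ix.pathways)),
        }
        for ix in intersections
    ]
    return pd.DataFrame(rows, columns=["combination", "n_pathways", "pathways"])
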