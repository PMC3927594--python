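"""Microsynteny classification of sRNA family models.

Microsynteny — conservation of the protein-coding genes immediately
flanking an sRNA locus — decays faster than sequence similarity and so
grades how deeply a family's genomic context is conserved:

* type I   (complete):   every member conserves both flanks;
* type II  (extensive):  most members (default >= 2/3) conserve both
  flanks, with a few exceptions;
* type III (partial):    all members conserve exactly one, and the
  same, flank;
* type IV  (fragmented): only member subsets (>= 2) share conserved
  flanks;
* NA for stand-alone families (< 2 members).

Flank conservation is protein homology of the translated neighbouring
genes against the pivot's flanks at E <= 1e-6.  The decision table is
total: every per-member flank pattern maps to exactly one type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seqio import AnnotationRecord, SequenceRecord
from .homsearch import Locus, evalue
from .assess import (
    AssessmentConfig,
    DEFAULT_CONFIG,
    nearest_flanks,
    protein_local_align,
    _translate,
    _PROT_LAMBDA,
    _PROT_K,
)

__all__ = ["MicrosyntenyCall", "flank_genes", "classify_microsynteny", "classify_matrix"]


@dataclass
class MicrosyntenyCall:
    family_id: str
    type: str  # I | II | III | IV | NA
    flank_matrix: list[str] = field(default_factory=list)  # per member: both|up|down|none
    parameters: dict = field(default_factory=dict)


def flank_genes(
    locus: Locus, annotations: list[AnnotationRecord], exclude_overlapping: bool = True
) -> tuple[AnnotationRecord | None, AnnotationRecord | None]:
    """Nearest non-overlapping protein-coding gene up- and downstream of
    a locus, in the locus' own orientation (None for an absent side)."""
    return nearest_flanks(locus, annotations, exclude_overlapping)


def _flank_status(
    member_locus: Locus,
    pivot_flanks,
    annotations: list[AnnotationRecord],
    genomes: dict[str, SequenceRecord],
    emax: float,
    max_dist: int | None = None,
) -> str:
    up_p, down_p = pivot_flanks
    up_m, down_m = nearest_flanks(member_locus, annotations,
                                  max_dist=max_dist)
    conserved = {"up": False, "down": False}
    for side, pg, mg in (("up", up_p, up_m), ("down", down_p, down_m)):
        if pg is None or mg is None:
            continue
        prot_p = _translate(pg, genomes[pg.seqid])
        prot_m = _translate(mg, genomes[mg.seqid])
        if not prot_p or not prot_m:
            continue
        s = protein_local_align(prot_p, prot_m)
        E = evalue(s, len(prot_p), len(prot_m), _PROT_LAMBDA, _PROT_K)
        if E <= emax:
            conserved[side] = True
    if conserved["up"] and conserved["down"]:
        return "both"
    if conserved["up"]:
        return "up"
    if conserved["down"]:
        return "down"
    return "none"


def classify_matrix(statuses: list[str], majority: float = 2 / 3) -> str:
    """Map a per-member flank matrix to a microsynteny type.

    ``statuses`` holds one of both/up/down/none per non-pivot member.
    The table is total, deterministic and order-independent, checked in
    sequence: I if every member is ``both``; II if at least the
    ``majority`` fraction is ``both``; III if every member conserves
    exactly one and the same flank; IV otherwise (conservation limited
    to member subsets).
    """
    if not statuses:
        return "NA"
    n = len(statuses)
    n_both = sum(1 for s in statuses if s == "both")
    if n_both == n:
        return "I"
    if n_both / n >= majority:
        return "II"
    if all(s == "up" for s in statuses) or all(s == "down" for s in statuses):
        return "III"
    return "IV"


def classify_microsynteny(
    family,
    annotations: list[AnnotationRecord],
    genomes: list[SequenceRecord],
    config: AssessmentConfig = DEFAULT_CONFIG,
    majority: float = 2 / 3,
) -> MicrosyntenyCall:
    """Classify a family's microsynteny from member flank conservation.

    Each member's flanks are compared against the pivot's flanks
    (protein homology at the synteny E-value threshold); members whose
    replicon lacks annotation are excluded and logged in the call's
    parameters.  Families with < 2 usable members are NA (stand-alone).
    """
    by_id = {g.id: g for g in genomes}
    members = [m for m in family.members if m.locus is not None]
    if len(members) < 2:
        return MicrosyntenyCall(family.family_id, "NA",
                                parameters={"reason": "stand-alone"})
    annotated_seqids = {a.seqid for a in annotations}
    pivot_locus = members[0].locus
    pivot_flanks = nearest_flanks(pivot_locus, annotations,
                                  max_dist=config.flank_max_dist_nt)
    statuses = []
    excluded = []
    for m in members[1:]:
        if m.locus.seqid not in annotated_seqids:
            excluded.append(m.id)
            continue
        statuses.append(
            _flank_status(m.locus, pivot_flanks, annotations, by_id,
                          config.synteny_evalue_max,
                          max_dist=config.flank_max_dist_nt)
        )
    if not statuses:
        return MicrosyntenyCall(family.family_id, "NA",
                                parameters={"reason": "no_annotated_members",
                                            "excluded": excluded})
    t = classify_matrix(statuses, majority)
    call = MicrosyntenyCall(
        family.family_id,
        t,
        flank_matrix=statuses,
        parameters={
            "majority": majority,
            "synteny_evalue_max": config.synteny_evalue_max,
            "excluded": excluded,
        },
    )
    return call


def calls_to_frame(calls: list[MicrosyntenyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": c.family_id,
                "type": c.type,
                "flank_matrix": ",".join(c.flank_matrix),
            }
            for c in calls
        ]
    )
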