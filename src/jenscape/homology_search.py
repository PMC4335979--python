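"""Two-step reciprocal homology screen across species proteomes.

Family membership is decided the way reciprocal-best-hit ortholog screens
do it: every seed protein is searched against each other proteome with a
local-alignment scan under an E-value cutoff (default 1e-10); the top
forward hit is then searched back against the full seed proteome, and it
is admitted iff its top reciprocal hit belongs to the seed set.  Every
admitted member records the forward and reciprocal hits that admitted it;
discarded candidates go to a rejects table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .io_formats import SeqRecord
from .pairwise import (KarlinAltschulParams, ScoringScheme, _default_scheme,
                       align_score, evalue)

DEFAULT_CUTOFF = 1e-10


@dataclass
class SearchHit:
    query_id: str
    subject_id: str
    subject_species: str
    raw_score: float
    evalue: float

    @property
    def sort_key(self):
        return (self.evalue, -self.raw_score, self.subject_id)


def search_proteome(query: SeqRecord, proteome: List[SeqRecord],
                    scheme: Optional[ScoringScheme] = None,
                    cutoff: float = DEFAULT_CUTOFF) -> List[SearchHit]:
    """Local-align ``query`` against every subject; keep hits with
    E <= cutoff, sorted by (E-value asc, score desc, subject id asc).

    The database length n in the E-value is the proteome's total residue
    count, as in a database search.
    """
    if not proteome:
        raise ValueError("search_proteome: empty proteome")
    scheme = scheme or _default_scheme()
    n_db = sum(len(rec) for rec in proteome)
    hits = []
    for subject in proteome:
        score = align_score(query, subject, scheme, mode="local")
        params = KarlinAltschulParams(m=len(query), n=n_db)
        e = evalue(score, params)
        if e <= cutoff:
            hits.append(SearchHit(query.id, subject.id, subject.species,
                                  score, e))
    hits.sort(key=lambda h: h.sort_key)
    return hits


@dataclass
class MemberProvenance:
    forward: SearchHit
    reciprocal: SearchHit  # the top reciprocal hit (a seed member)
    seed_id: str


@dataclass
class RejectedHit:
    forward: SearchHit
    reciprocal_top: Optional[SearchHit]  # None if nothing passed the cutoff
    reason: str


@dataclass
class HomologFamily:
    seed_species: str
    seed_ids: Set[str]
    members: Dict[str, Set[str]]  # species -> gene ids
    provenance: Dict[Tuple[str, str], List[MemberProvenance]] = field(default_factory=dict)
    rejects: List[RejectedHit] = field(default_factory=list)

    def all_member_ids(self) -> Set[str]:
        out = set()
        for ids in self.members.values():
            out |= ids
        return out


def reciprocal_screen(seed_ids: Set[str], seed_proteome: List[SeqRecord],
                      other_proteomes: Dict[str, List[SeqRecord]],
                      scheme: Optional[ScoringScheme] = None,
                      cutoff: float = DEFAULT_CUTOFF) -> HomologFamily:
    """Two-step reciprocal screen.

    Step 1: each seed is searched against each other species' proteome and
    the single top hit passing the cutoff is taken forward.  Step 2: that
    hit is searched back against the full seed proteome; it is admitted
    iff its top reciprocal hit is a seed.  The result is invariant to
    proteome record order (the canonical hit order breaks all ties).
    """
    scheme = scheme or _default_scheme()
    seed_ids = set(seed_ids)
    by_id = {rec.id: rec for rec in seed_proteome}
    missing = seed_ids - set(by_id)
    if missing:
        raise ValueError(f"seed ids not in seed proteome: {sorted(missing)}")
    seed_species = seed_proteome[0].species if seed_proteome else ""

    family = HomologFamily(
        seed_species=seed_species,
        seed_ids=seed_ids,
        members={seed_species: set(seed_ids)},
    )
    checked: Dict[str, Optional[SearchHit]] = {}
    for seed_id in sorted(seed_ids):
        seed = by_id[seed_id]
        for species in sorted(other_proteomes):
            proteome = other_proteomes[species]
            if not proteome:
                continue
            hits = search_proteome(seed, proteome, scheme, cutoff)
            if not hits:
                continue
            # the "top hit", with exact ties at the best score all kept —
            # otherwise identical paralogs could never all be recovered
            tops = [h for h in hits if (h.evalue, h.raw_score) ==
                    (hits[0].evalue, hits[0].raw_score)]
            by_subject = {rec.id: rec for rec in proteome}
            for top in tops:
                cand = by_subject[top.subject_id]
                if cand.id not in checked:
                    back = search_proteome(cand, seed_proteome, scheme, cutoff)
                    back_tops = [h for h in back if (h.evalue, h.raw_score) ==
                                 (back[0].evalue, back[0].raw_score)] if back else []
                    checked[cand.id] = back_tops
                back_tops = checked[cand.id]
                recip = next((h for h in back_tops if h.subject_id in seed_ids),
                             None)
                if recip is not None:
                    family.members.setdefault(species, set()).add(cand.id)
                    family.provenance.setdefault((species, cand.id), []).append(
                        MemberProvenance(top, recip, seed_id))
                else:
                    reason = ("no reciprocal hit passed the cutoff"
                              if not back_tops else
                              f"reciprocal top hit {back_tops[0].subject_id!r} "
                              "is not a seed")
                    family.rejects.append(
                        RejectedHit(top, back_tops[0] if back_tops else None,
                                    reason))
    return family
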