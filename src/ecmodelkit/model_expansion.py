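"""Enzyme-resolved model expansion.

An enzyme-constrained model needs one flux variable per (reaction,
direction, enzyme) triple, because forward and reverse catalysis can have
different turnover numbers and each isozyme has its own weight and kcat.
Two rewrites achieve this:

* ``split_reversible`` — each reversible internal reaction ``R`` becomes an
  irreversible ``R`` (bounds ``[0, ub]``) plus ``R_reverse`` with negated
  stoichiometry and bounds ``[0, -lb]``;
* ``split_isozymes`` — each reaction whose GPR is an ``or`` of k enzymes
  becomes k copies ``R_num1`` ... ``R_numk``, one enzyme each.

Exchange reactions keep their native (possibly negative) bounds and are
never split: they carry no enzyme and the uptake sign convention is used
directly by the analyses.  A :class:`SplitMap` records the provenance of
every split reaction so fluxes can be aggregated back onto the original
network.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import EcModelKitError
from .gem_io import ModelDocument, ReactionRecord
from .gpr_curation import parse_gpr

REVERSE_SUFFIX = "_reverse"


@dataclass(frozen=True)
class SplitOrigin:
    original_id: str
    direction: str  # "fwd" | "rev"
    enzyme_index: int | None = None


@dataclass
class SplitMap:
    """Maps each split reaction id to its origin; composable across steps."""

    origin: dict[str, SplitOrigin]

    def members(self, original_id: str) -> list[str]:
        return [sid for sid, o in self.origin.items() if o.original_id == original_id]

    def compose(self, later: "SplitMap") -> "SplitMap":
        """Provenance of ``later`` applied after ``self``."""
        out: dict[str, SplitOrigin] = {}
        for sid, o in later.origin.items():
            base = self.origin.get(o.original_id)
            if base is None:
                out[sid] = o
            else:
                direction = "rev" if "rev" in (base.direction, o.direction) else "fwd"
                out[sid] = SplitOrigin(base.original_id, direction, o.enzyme_index if o.enzyme_index is not None else base.enzyme_index)
        return SplitMap(out)


def split_reversible(model: ModelDocument) -> tuple[ModelDocument, SplitMap]:
    """Split reversible internal reactions into forward/reverse halves."""
    reactions: list[ReactionRecord] = []
    origin: dict[str, SplitOrigin] = {}
    for r in model.reactions:
        if r.lower_bound < 0 and not r.is_exchange:
            fwd = replace(r, lower_bound=0.0, upper_bound=r.upper_bound)
            rev = replace(
                r,
                id=r.id + REVERSE_SUFFIX,
                stoichiometry={m: -c for m, c in r.stoichiometry.items()},
                lower_bound=0.0,
                upper_bound=-r.lower_bound,
            )
            reactions.extend([fwd, rev])
            origin[fwd.id] = SplitOrigin(r.id, "fwd")
            origin[rev.id] = SplitOrigin(r.id, "rev")
        else:
            reactions.append(r)
            origin[r.id] = SplitOrigin(r.id, "fwd")
    out = model.copy()
    out.reactions = reactions
    return out, SplitMap(origin)


def split_isozymes(model: ModelDocument) -> tuple[ModelDocument, SplitMap]:
    """Give every isozyme its own reaction copy, ``<id>_num1`` ... ``<id>_numk``.

    Enzyme order is the deterministic DNF order of :func:`parse_gpr`.
    Exchange reactions are never split.
    """
    reactions: list[ReactionRecord] = []
    origin: dict[str, SplitOrigin] = {}
    objective = dict(model.objective)
    for r in model.reactions:
        expr = parse_gpr(r.gpr_text) if not r.is_exchange else None
        if expr is not None and len(expr) > 1:
            for i, cx in enumerate(expr.enzymes, start=1):
                rid = f"{r.id}_num{i}"
                reactions.append(replace(r, id=rid, gpr_text=" and ".join(cx)))
                origin[rid] = SplitOrigin(r.id, "fwd", enzyme_index=i)
            if r.id in objective:
                raise EcModelKitError(f"objective reaction {r.id} has isozymes; split is ambiguous")
        else:
            reactions.append(r)
            origin[r.id] = SplitOrigin(r.id, "fwd")
    out = model.copy()
    out.reactions = reactions
    out.objective = objective
    return out, SplitMap(origin)


def expand_model(model: ModelDocument) -> tuple[ModelDocument, SplitMap]:
    """Reversible split followed by isozyme split, with composed provenance."""
    m1, map1 = split_reversible(model)
    m2, map2 = split_isozymes(m1)
    return m2, map1.compose(map2)


def aggregate_flux(fluxes: dict[str, float], split_map: SplitMap) -> dict[str, float]:
    """Net flux per original reaction: sum of forward copies minus reverse copies."""
    unknown = set(split_map.origin) - set(fluxes)
    if unknown:
        raise EcModelKitError(f"solution missing split reactions: {sorted(unknown)}")
    out: dict[str, float] = {}
    for sid, o in split_map.origin.items():
        sign = -1.0 if o.direction == "rev" else 1.0
        out[o.original_id] = out.get(o.original_id, 0.0) + sign * fluxes[sid]
    return out


def write_split_map(split_map: SplitMap, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "split_id": sid,
                "original_id": o.original_id,
                "direction": o.direction,
                "enzyme_index": "" if o.enzyme_index is None else o.enzyme_index,
            }
            for sid, o in sorted(split_map.origin.items())
        ]
    ).to_csv(path, sep="\t", index=False)
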