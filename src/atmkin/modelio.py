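"""Plain-text model exchange format (lossless round trip).

The format is line-oriented with ``;``-separated fields::

    # atmkin model v1
    model atm-reference

    [species]
    # id ; name ; form ; mobility ; initial ; composition
    KAP1 ; KAP-1 ; free ; shuttling ; 1.0 ; KAP1=1

    [groups]
    kinase_full ; ATM_mon_A=1, ATM_mon_F=1, ...

    [reactions]
    # id : reactants -> products ; law(params) ; gates ; modifiers
    hp1_disp : HP1b_H3K9me3 -> pHP1b + H3K9me3 ; mass_action(k=2.0) ; relaxation(h=2.0) ; CK2

An empty reactant/product side is written ``-``; numbers use ``repr`` so a
write/read cycle reproduces the network exactly.
"""

from __future__ import annotations

import re
from pathlib import Path

from .network import (
    Gate,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
    ValidationError,
)

__all__ = ["write_model", "read_model", "dumps_model", "loads_model"]

_HEADER = "# atmkin model v1"


def _fmt_num(x: float) -> str:
    return repr(float(x))


def _fmt_side(side) -> str:
    if not side:
        return "-"
    parts = []
    for sp, n in side.items():
        parts.append(f"{n} {sp}" if n != 1 else sp)
    return " + ".join(parts)


def _parse_side(text: str, rid: str) -> dict[str, int]:
    text = text.strip()
    if text == "-" or not text:
        return {}
    out: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        m = re.fullmatch(r"(?:(\d+)\s+)?(\S+)", term)
        if not m:
            raise ValidationError(f"reaction {rid!r}: cannot parse term {term!r}")
        n = int(m.group(1) or 1)
        sp = m.group(2)
        out[sp] = out.get(sp, 0) + n
    return out


def _fmt_law(law: RateLaw) -> str:
    if law.form == "mass_action":
        return f"mass_action(k={_fmt_num(law.k)})"
    return f"michaelis_menten(vmax={_fmt_num(law.vmax)}, km={_fmt_num(law.km)})"


def _fmt_gate(gate: Gate) -> str:
    if gate.kind == "relaxation":
        return f"relaxation(h={_fmt_num(gate.h)})"
    return f"{gate.kind}(K={_fmt_num(gate.K)})"


_CALL_RE = re.compile(r"(\w+)\((.*)\)")


def _parse_call(text: str, where: str) -> tuple[str, dict[str, float]]:
    m = _CALL_RE.fullmatch(text.strip())
    if not m:
        raise ValidationError(f"{where}: cannot parse {text!r}")
    kwargs = {}
    body = m.group(2).strip()
    if body:
        for part in body.split(","):
            k, _, v = part.partition("=")
            kwargs[k.strip()] = float(v)
    return m.group(1), kwargs


def _parse_law(text: str, rid: str, gates: tuple[Gate, ...]) -> RateLaw:
    name, kw = _parse_call(text, f"reaction {rid!r} rate law")
    if name == "mass_action":
        return RateLaw("mass_action", k=kw["k"], gates=gates)
    if name == "michaelis_menten":
        return RateLaw("michaelis_menten", vmax=kw["vmax"], km=kw["km"], gates=gates)
    raise ValidationError(f"reaction {rid!r}: unknown rate law {name!r}")


def _parse_gates(text: str, rid: str) -> tuple[Gate, ...]:
    text = text.strip()
    if not text or text == "-":
        return ()
    gates = []
    for part in text.split(","):
        # careful: gate args contain no commas, so a plain split is safe
        name, kw = _parse_call(part, f"reaction {rid!r} gate")
        if name == "relaxation":
            gates.append(Gate("relaxation", h=kw.get("h", 1.0)))
        elif name in ("ros", "dsb"):
            gates.append(Gate(name, K=kw.get("K", 1.0)))
        else:
            raise ValidationError(f"reaction {rid!r}: unknown gate {name!r}")
    return tuple(gates)


def dumps_model(network: ReactionNetwork) -> str:
    lines = [_HEADER, f"model {network.name}", ""]
    lines.append("[species]")
    lines.append("# id ; name ; form ; mobility ; initial ; composition")
    for s in network.species:
        comp = ",".join(f"{m}={n}" for m, n in s.composition.items()) or "-"
        lines.append(
            f"{s.id} ; {s.name} ; {s.form} ; {s.mobility} ; "
            f"{_fmt_num(s.initial_amount)} ; {comp}"
        )
    if network.groups:
        lines.append("")
        lines.append("[groups]")
        for g, weights in network.groups.items():
            ws = ", ".join(f"{sp}={_fmt_num(w)}" for sp, w in weights.items())
            lines.append(f"{g} ; {ws}")
    lines.append("")
    lines.append("[reactions]")
    lines.append("# id : reactants -> products ; law(params) ; gates ; modifiers")
    for r in network.reactions:
        gates = ", ".join(_fmt_gate(g) for g in r.rate_law.gates) or "-"
        mods = ", ".join(r.modifiers) or "-"
        lines.append(
            f"{r.id} : {_fmt_side(r.reactants)} -> {_fmt_side(r.products)} ; "
            f"{_fmt_law(r.rate_law)} ; {gates} ; {mods}"
        )
    return "\n".join(lines) + "\n"


def loads_model(text: str) -> ReactionNetwork:
    lines = [ln.strip() for ln in text.splitlines()]
    if not lines or lines[0] != _HEADER:
        raise ValidationError(f"not an atmkin model file (missing {_HEADER!r})")
    name = "model"
    section = None
    species: list[Species] = []
    groups: dict[str, dict[str, float]] = {}
    reactions: list[Reaction] = []
    for ln in lines[1:]:
        if not ln or ln.startswith("#"):
            continue
        if ln.startswith("model "):
            name = ln[len("model "):].strip()
            continue
        if ln.startswith("["):
            section = ln.strip("[]")
            if section not in ("species", "groups", "reactions"):
                raise ValidationError(f"unknown section {section!r}")
            continue
        if section == "species":
            fields = [f.strip() for f in ln.split(";")]
            if len(fields) != 6:
                raise ValidationError(f"bad species line: {ln!r}")
            sid, sname, form, mobility, init, comp = fields
            composition = {}
            if comp != "-":
                for part in comp.split(","):
                    k, _, v = part.partition("=")
                    composition[k.strip()] = int(v)
            species.append(
                Species(sid, sname, form, mobility, float(init), composition)
            )
        elif section == "groups":
            gname, _, body = ln.partition(";")
            weights = {}
            for part in body.split(","):
                k, _, v = part.partition("=")
                weights[k.strip()] = float(v)
            groups[gname.strip()] = weights
        elif section == "reactions":
            rid, _, rest = ln.partition(":")
            rid = rid.strip()
            fields = [f.strip() for f in rest.split(";")]
            if len(fields) != 4:
                raise ValidationError(f"bad reaction line: {ln!r}")
            eq, law_s, gates_s, mods_s = fields
            lhs, arrow, rhs = eq.partition("->")
            if not arrow:
                raise ValidationError(f"reaction {rid!r}: missing '->'")
            gates = _parse_gates(gates_s, rid)
            law = _parse_law(law_s, rid, gates)
            mods = ()
            if mods_s and mods_s != "-":
                mods = tuple(m.strip() for m in mods_s.split(","))
            reactions.append(
                Reaction(
                    rid,
                    _parse_side(lhs, rid),
                    _parse_side(rhs, rid),
                    law,
                    mods,
                )
            )
        else:
            raise ValidationError(f"content outside any section: {ln!r}")
    return ReactionNetwork(species, reactions, groups, name=name)


def write_model(network: ReactionNetwork, path) -> None:
    Path(path).write_text(dumps_model(network))


def read_model(path) -> ReactionNetwork:
    return loads_model(Path(path).read_text())
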