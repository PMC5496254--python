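"""Plain-text reaction grammar: parse and emit delayed reaction systems.

One reaction per line::

    ProA + *Ind --[0.002]--> A + ProA
    X --[1.0]-->
    RB --[0.1]--> RB + PB(gamma:2,1)

``*`` marks a catalytic reactant (counted in the propensity, not consumed).
The bracketed number is the rate constant.  A parenthesized annotation on a
product attaches a delay: ``(5)`` constant, ``(gamma:shape,scale)``,
``(gauss:mean,sd)``, ``(exp:rate)``.  An empty (or ``∅``) right-hand side
means pure degradation.  ``#`` starts a comment; ``species NAME = COUNT``
lines set initial populations.  Typographic dashes (as found in copied
text) are normalized before tokenizing, so ``ProA + *Ind –[0.002]– > A``
parses too.
"""

from __future__ import annotations

import re
from typing import Iterable

from .reactions import DelaySpec, Product, Reactant, Reaction, ReactionSystem

__all__ = ["parse_reactions", "format_reactions", "ReactionTextError"]


class ReactionTextError(ValueError):
    """Malformed reaction text; carries the offending line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


_DASHES = str.maketrans({"–": "-", "—": "-", "−": "-"})
_ARROW_RE = re.compile(r"-+\s*\[([^\]]*)\]\s*-+\s*>")
_SPECIES_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_.]*")
_POPULATION_RE = re.compile(r"^species\s+([A-Za-z_][A-Za-z0-9_.]*)\s*=\s*(\d+)$")

_DELAY_ALIASES = {
    "gamma": ("gamma", ("shape", "scale")),
    "gauss": ("gaussian", ("mean", "sd")),
    "gaussian": ("gaussian", ("mean", "sd")),
    "exp": ("exponential", ("rate",)),
    "exponential": ("exponential", ("rate",)),
}


def parse_reactions(text: str) -> ReactionSystem:
    """Parse reaction text into a :class:`ReactionSystem`.

    Species are declared implicitly by first use with an initial count of 0
    unless a ``species NAME = COUNT`` line says otherwise.
    """
    species: dict[str, int] = {}
    declared_counts: dict[str, int] = {}
    reactions: list[Reaction] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        pop = _POPULATION_RE.match(line)
        if pop:
            declared_counts[pop.group(1)] = int(pop.group(2))
            species.setdefault(pop.group(1), 0)
            continue
        reaction = _parse_reaction_line(line, lineno)
        for name in reaction.species_names():
            species.setdefault(name, 0)
        reactions.append(reaction)

    species.update(declared_counts)
    return ReactionSystem(species=species, reactions=reactions)


def _parse_reaction_line(line: str, lineno: int) -> Reaction:
    line = line.translate(_DASHES)
    match = _ARROW_RE.search(line)
    if match is None:
        raise ReactionTextError(lineno, f"no rate arrow '--[c]-->' found in {line!r}")
    rate_text = match.group(1).strip()
    try:
        rate = float(rate_text)
    except ValueError:
        raise ReactionTextError(lineno, f"malformed rate constant {rate_text!r}") from None
    if rate < 0:
        raise ReactionTextError(lineno, f"rate constant must be >= 0, got {rate}")

    lhs, rhs = line[: match.start()], line[match.end() :]
    reactants = _parse_side(lhs, lineno, side="reactant")
    products = _parse_side(rhs, lineno, side="product")
    if not reactants and not products:
        raise ReactionTextError(lineno, "reaction has neither reactants nor products")
    try:
        return Reaction(reactants=tuple(reactants), products=tuple(products), rate_constant=rate)
    except ValueError as exc:
        raise ReactionTextError(lineno, str(exc)) from None


def _parse_side(text: str, lineno: int, side: str):
    text = text.strip()
    if not text or text in ("∅", "0"):
        return []
    terms = [t.strip() for t in text.split("+")]
    parsed = []
    for term in terms:
        if not term:
            raise ReactionTextError(lineno, f"dangling '+' on {side} side")
        parsed.append(_parse_term(term, lineno, side))
    return parsed


def _parse_term(term: str, lineno: int, side: str):
    catalyst = False
    if term.startswith("*"):
        if side == "product":
            raise ReactionTextError(lineno, "catalyst marker '*' is only valid on reactants")
        catalyst = True
        term = term[1:].strip()

    stoich = 1
    stoich_match = re.match(r"^(\d+)\s+(.*)$", term)
    if stoich_match:
        stoich = int(stoich_match.group(1))
        term = stoich_match.group(2).strip()

    name_match = _SPECIES_RE.match(term)
    if name_match is None or name_match.start() != 0:
        raise ReactionTextError(lineno, f"cannot parse species term {term!r}")
    name = name_match.group(0)
    rest = term[name_match.end() :].strip()

    if side == "reactant":
        if rest:
            raise ReactionTextError(lineno, f"unexpected trailing text {rest!r} after reactant {name!r}")
        return Reactant(name, stoich, catalyst)

    delay = DelaySpec.none()
    if rest:
        if not (rest.startswith("(") and rest.endswith(")")):
            raise ReactionTextError(lineno, f"unexpected trailing text {rest!r} after product {name!r}")
        delay = _parse_delay(rest[1:-1].strip(), lineno)
    return Product(name, stoich, delay)


def _parse_delay(spec_text: str, lineno: int) -> DelaySpec:
    if ":" not in spec_text:
        try:
            return DelaySpec.constant(float(spec_text))
        except ValueError:
            raise ReactionTextError(lineno, f"malformed constant delay {spec_text!r}") from None
    kind_text, _, args_text = spec_text.partition(":")
    kind_text = kind_text.strip().lower()
    if kind_text not in _DELAY_ALIASES:
        raise ReactionTextError(
            lineno, f"unknown delay kind {kind_text!r}; expected one of {sorted(_DELAY_ALIASES)}"
        )
    kind, param_names = _DELAY_ALIASES[kind_text]
    arg_parts = [a.strip() for a in args_text.split(",")]
    if len(arg_parts) != len(param_names):
        raise ReactionTextError(
            lineno,
            f"delay kind {kind_text!r} takes {len(param_names)} parameter(s) "
            f"({', '.join(param_names)}), got {len(arg_parts)}",
        )
    try:
        values = [float(a) for a in arg_parts]
    except ValueError:
        raise ReactionTextError(lineno, f"malformed delay parameters {args_text!r}") from None
    try:
        return DelaySpec(kind, dict(zip(param_names, values)))
    except ValueError as exc:
        raise ReactionTextError(lineno, str(exc)) from None


# ---------------------------------------------------------------------------
# Formatting


def format_reactions(system: ReactionSystem, *, populations: bool = True) -> str:
    """Emit ``system`` in the text grammar; re-parses to an equivalent system."""
    lines: list[str] = []
    if populations:
        for name, count in system.species.items():
            if count != 0:
                lines.append(f"species {name} = {count}")
        if lines:
            lines.append("")
    for reaction in system.reactions:
        lines.append(_format_reaction(reaction))
    return "\n".join(lines) + ("\n" if lines else "")


def _format_reaction(reaction: Reaction) -> str:
    lhs = " + ".join(_format_reactant(r) for r in reaction.reactants)
    rhs = " + ".join(_format_product(p) for p in reaction.products)
    rate = _format_number(reaction.rate_constant)
    return f"{lhs} --[{rate}]--> {rhs}".rstrip()


def _format_reactant(r: Reactant) -> str:
    prefix = "*" if r.catalyst else ""
    stoich = f"{r.stoichiometry} " if r.stoichiometry != 1 else ""
    return f"{prefix}{stoich}{r.species}"


def _format_product(p: Product) -> str:
    stoich = f"{p.stoichiometry} " if p.stoichiometry != 1 else ""
    return f"{stoich}{p.species}{_format_delay(p.delay)}"


def _format_delay(delay: DelaySpec) -> str:
    if delay.kind == "none":
        return ""
    if delay.kind == "constant":
        return f"({_format_number(delay.params['value'])})"
    if delay.kind == "gamma":
        return f"(gamma:{_format_number(delay.params['shape'])},{_format_number(delay.params['scale'])})"
    if delay.kind == "gaussian":
        return f"(gauss:{_format_number(delay.params['mean'])},{_format_number(delay.params['sd'])})"
    return f"(exp:{_format_number(delay.params['rate'])})"


def _format_number(x: float) -> str:
    # repr() is the shortest exact round-trip representation in Python 3
    return repr(float(x))
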