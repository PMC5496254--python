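"""Compile a signed gene network into a delayed reaction system.

Each gene ``X`` is represented by three kinds of species: promoter forms,
an RNA ``RX`` and a protein ``PX``.  A gene with incoming regulators gets
one promoter *site* per regulator ``Y`` with a free form ``ProX.NoY`` and a
bound form ``ProX.Y``; a gene without regulators keeps a single constitutive
promoter ``ProX``.

The compiled system contains, per gene:

1. translation ``RX -> RX + PX`` (RNA catalytic; protein delayed), RNA decay
   ``RX -> 0`` and protein decay ``PX -> 0``;
2. per incoming regulator ``Y``: binding ``PY + ProX.NoY -> ProX.Y`` and
   unbinding ``ProX.Y -> ProX.NoY + PY``;
3. one transcription reaction per non-empty subset of X's bound-activator
   forms; every transcription reaction also requires each *free* repressor
   site catalytically, so a bound repressor silences the gene.  Promoter
   forms are re-released with the promoter delay, the RNA product carries
   the RNA delay.  A gene with no activators gets a single basal
   transcription reaction instead.
"""

from __future__ import annotations

from itertools import combinations
from typing import Callable, Iterable, Sequence

from .network import ACTIVATION, GeneNetwork
from .reactions import (
    DelayParams,
    Product,
    RateParams,
    Reactant,
    Reaction,
    ReactionSystem,
    WaitListEntry,
)

__all__ = [
    "compile_network",
    "transcription_combinations",
    "count_reactions",
    "rna_species",
    "protein_species",
    "promoter_free",
    "promoter_bound",
    "promoter_constitutive",
]


# -- species naming dialect -------------------------------------------------

def rna_species(gene: str) -> str:
    return f"R{gene}"


def protein_species(gene: str) -> str:
    return f"P{gene}"


def promoter_free(gene: str, regulator: str) -> str:
    """Free promoter site of ``gene`` for ``regulator``."""
    return f"Pro{gene}.No{regulator}"


def promoter_bound(gene: str, regulator: str) -> str:
    """Regulator-bound promoter form ('intermediary product')."""
    return f"Pro{gene}.{regulator}"


def promoter_constitutive(gene: str) -> str:
    """Single promoter of a regulator-less gene."""
    return f"Pro{gene}"


def transcription_combinations(activators: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets of ``activators``, ordered by size then lexicographically.

    Each subset corresponds to one transcription reaction in which exactly
    the bound-activator forms of that subset drive expression.
    """
    if len(set(activators)) != len(activators):
        raise ValueError("activator list must be duplicate-free")
    ordered = sorted(activators)
    subsets: list[tuple[str, ...]] = []
    for size in range(1, len(ordered) + 1):
        subsets.extend(combinations(ordered, size))
    return subsets


def count_reactions(network: GeneNetwork) -> int:
    """Number of reactions :func:`compile_network` will emit.

    Per gene: 3 translation/degradation reactions, 2 per incoming edge
    (binding + unbinding), and ``2**a - 1`` transcription reactions for
    ``a`` activators (or a single basal one when ``a == 0``).
    """
    total = 0
    for gene in network.nodes:
        a = len(network.activators(gene))
        total += 3 + 2 * network.in_degree(gene)
        total += (2**a - 1) if a > 0 else 1
    return total


def compile_network(
    network: GeneNetwork,
    rates: RateParams | None = None,
    delays: DelayParams | None = None,
    *,
    repressors_block: bool = True,
    subset_rate: Callable[[str, tuple[str, ...]], float | None] | None = None,
    waitlist: Iterable[WaitListEntry] = (),
) -> ReactionSystem:
    """Translate a signed network into the full delayed reaction system.

    Parameters
    ----------
    network
        A fully signed :class:`~gnsim.network.GeneNetwork`.
    rates, delays
        Rate constants and delay specifications; defaults are used when
        omitted.
    repressors_block
        When True (default) every transcription reaction of a gene requires
        all of its free repressor sites catalytically, so any bound
        repressor sets the transcription propensity to zero.
    subset_rate
        Optional hook ``(gene, activator_subset) -> rate`` overriding the
        transcription rate of individual combination reactions; return
        ``None`` to keep the default.
    waitlist
        Initial scheduled molecule injections, passed through to the system.

    Initial populations: each promoter site/constitutive promoter starts at
    one copy (single gene copy); RNA and protein counts come from the
    network's node attributes.
    """
    network.require_signed()
    rates = rates or RateParams()
    delays = delays or DelayParams()

    species: dict[str, int] = {}
    reactions: list[Reaction] = []
    gene_species: dict[str, tuple[str, str]] = {}

    for gene in network.nodes:
        rna = rna_species(gene)
        prot = protein_species(gene)
        init_rna, init_protein = network.init_counts(gene)
        species[rna] = init_rna
        species[prot] = init_protein
        gene_species[gene] = (rna, prot)

    for gene in network.nodes:
        rna = rna_species(gene)
        prot = protein_species(gene)
        regulators = network.regulators(gene)
        activators = sorted(network.activators(gene))
        repressors = sorted(network.repressors(gene))

        # 1. translation and decay
        reactions.append(
            Reaction(
                reactants=(Reactant(rna, 1, catalyst=True),),
                products=(Product(prot, 1, delays.protein_delay),),
                rate_constant=rates.gene_rate("translation", gene),
                name=f"translation:{gene}",
            )
        )
        reactions.append(
            Reaction(
                reactants=(Reactant(rna, 1),),
                products=(),
                rate_constant=rates.gene_rate("rna_degradation", gene),
                name=f"rna_decay:{gene}",
            )
        )
        reactions.append(
            Reaction(
                reactants=(Reactant(prot, 1),),
                products=(),
                rate_constant=rates.gene_rate("protein_degradation", gene),
                name=f"protein_decay:{gene}",
            )
        )

        # 2. binding / unbinding, one site per incoming regulator
        for regulator, _sign in regulators:
            site = promoter_free(gene, regulator)
            bound = promoter_bound(gene, regulator)
            species[site] = 1
            species[bound] = 0
            reg_protein = protein_species(regulator)
            reactions.append(
                Reaction(
                    reactants=(Reactant(reg_protein, 1), Reactant(site, 1)),
                    products=(Product(bound, 1),),
                    rate_constant=rates.edge_rate("binding", regulator, gene),
                    name=f"binding:{regulator}->{gene}",
                )
            )
            reactions.append(
                Reaction(
                    reactants=(Reactant(bound, 1),),
                    products=(Product(site, 1), Product(reg_protein, 1)),
                    rate_constant=rates.edge_rate("unbinding", regulator, gene),
                    name=f"unbinding:{regulator}->{gene}",
                )
            )

        # 3. transcription
        base_rate = rates.gene_rate("transcription", gene)
        repressor_sites = (
            tuple(promoter_free(gene, z) for z in repressors) if repressors_block else ()
        )
        if activators:
            for subset in transcription_combinations(activators):
                promoter_forms = tuple(promoter_bound(gene, y) for y in subset) + repressor_sites
                rate = base_rate
                if subset_rate is not None:
                    override = subset_rate(gene, subset)
                    if override is not None:
                        rate = float(override)
                reactions.append(
                    _transcription_reaction(
                        promoter_forms, rna, rate, delays, f"transcription:{gene}:{'+'.join(subset)}"
                    )
                )
        elif repressors and repressors_block:
            # no activators: basal expression gated by the free repressor sites
            reactions.append(
                _transcription_reaction(
                    repressor_sites, rna, base_rate, delays, f"transcription:{gene}:basal"
                )
            )
        else:
            promoter = promoter_constitutive(gene)
            species[promoter] = 1
            reactions.append(
                _transcription_reaction(
                    (promoter,), rna, base_rate, delays, f"transcription:{gene}:basal"
                )
            )

    return ReactionSystem(
        species=species,
        reactions=reactions,
        waitlist=list(waitlist),
        gene_species=gene_species,
    )


def _transcription_reaction(
    promoter_forms: tuple[str, ...],
    rna: str,
    rate: float,
    delays: DelayParams,
    name: str,
) -> Reaction:
    """One transcription reaction: promoter forms catalytic, RNA delayed.

    Promoter forms are re-released as products carrying the promoter delay:
    with a non-zero promoter delay the engine takes them offline at firing
    time and restores them when the delay elapses (promoter occupancy).
    """
    reactants = tuple(Reactant(form, 1, catalyst=True) for form in promoter_forms)
    products = (Product(rna, 1, delays.rna_delay),) + tuple(
        Product(form, 1, delays.promoter_delay) for form in promoter_forms
    )
    return Reaction(reactants=reactants, products=products, rate_constant=rate, name=name)
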