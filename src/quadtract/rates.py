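"""Mutation-rate estimators, Ts/Tv ratio and the strand-collapsed
mutation spectrum.

Rates are simple per-unit-per-generation point estimates for a
mutation-accumulation design: events counted over a generation window
divided by (targets x generations), where targets are bases, genes, or
quadruplex sites.  The MA assumption (near-neutral fixation of new
mutations through repeated bottlenecks) is taken as given.  Display
formatting is round-half-even at two significant figures, matching how
such estimates are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

from .variants import Variant, VariantKind

PUBLISHED_GENOME_BASES = 100_000_000  # round genome size used in published-count reproduction
PUBLISHED_N_GENES = 20_400
PUBLISHED_WINDOW_GENERATIONS = 300


@dataclass(frozen=True)
class RateDenominators:
    genome_bases: int = PUBLISHED_GENOME_BASES
    n_genes: int = PUBLISHED_N_GENES
    n_g4_sites: int | None = None
    n_generations: int = PUBLISHED_WINDOW_GENERATIONS

    def __post_init__(self) -> None:
        for name in ("genome_bases", "n_genes", "n_generations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_g4_sites is not None and self.n_g4_sites <= 0:
            raise ValueError("n_g4_sites must be positive")


def format_sci(x: float, sig: int = 2) -> str:
    """Two-significant-figure scientific notation, round-half-even.

    >>> format_sci(94 / 3e10)
    '3.1 × 10^-9'
    """
    if x == 0:
        return "0"
    d = Decimal(repr(x))
    exponent = d.adjusted()
    mant = d.scaleb(-exponent).quantize(
        Decimal(1).scaleb(-(sig - 1)), rounding=ROUND_HALF_EVEN
    )
    if abs(mant) >= 10:  # rounding carried over (e.g. 9.96 -> 10)
        mant = (mant / 10).quantize(
            Decimal(1).scaleb(-(sig - 1)), rounding=ROUND_HALF_EVEN
        )
        exponent += 1
    return f"{mant} × 10^{exponent}"


def round_sig(x: float, sig: int = 2) -> float:
    """Numeric value of ``x`` rounded to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    d = Decimal(repr(x))
    q = d.scaleb(-d.adjusted()).quantize(
        Decimal(1).scaleb(-(sig - 1)), rounding=ROUND_HALF_EVEN
    ).scaleb(d.adjusted())
    return float(q)


@dataclass(frozen=True)
class RateEstimate:
    numerator: int
    denominator_kind: str  # per_base | per_gene | per_site
    denominator: int
    n_generations: int
    rate: float

    @property
    def display(self) -> str:
        return format_sci(self.rate)


def per_base_rate(n: int, denom: RateDenominators) -> RateEstimate:
    """Events per base per generation over the window."""
    if n < 0:
        raise ValueError("count must be >= 0")
    rate = n / (denom.genome_bases * denom.n_generations)
    return RateEstimate(n, "per_base", denom.genome_bases, denom.n_generations, rate)


def per_gene_rate(n_genes_hit: int, denom: RateDenominators) -> RateEstimate:
    if n_genes_hit < 0:
        raise ValueError("count must be >= 0")
    rate = n_genes_hit / (denom.n_genes * denom.n_generations)
    return RateEstimate(n_genes_hit, "per_gene", denom.n_genes, denom.n_generations, rate)


def per_site_rate(
    n_events: int, n_sites: int, denom: RateDenominators
) -> RateEstimate:
    if n_events < 0:
        raise ValueError("count must be >= 0")
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    rate = n_events / (n_sites * denom.n_generations)
    return RateEstimate(n_events, "per_site", n_sites, denom.n_generations, rate)


# ----------------------------------------------------------------------
# substitution spectrum

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

# strand-collapsed class labels keyed by the pair seen on either strand
SPECTRUM_CLASSES = (
    "A:T→T:A", "A:T→C:G", "A:T→G:C", "G:C→A:T", "G:C→T:A", "G:C→C:G",
)


def _spectrum_class(ref: str, alt: str) -> str:
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMP or alt not in _COMP or ref == alt:
        raise ValueError(f"invalid substitution allele pair {ref}->{alt}")
    if ref in "TC":  # collapse to the A/G-reference representative
        ref, alt = _COMP[ref], _COMP[alt]
    pair = {"A": "A:T", "G": "G:C"}[ref]
    target = {"A": "A:T", "T": "T:A", "C": "C:G", "G": "G:C"}[alt]
    return f"{pair}→{target}"


class SpectrumTable(dict):
    """Counts over the six strand-collapsed substitution classes."""

    @property
    def transitions(self) -> int:
        return self.get("A:T→G:C", 0) + self.get("G:C→A:T", 0)

    @property
    def transversions(self) -> int:
        return sum(self.values()) - self.transitions

    def per_base_rates(
        self, genome_at_bases: int, genome_gc_bases: int, n_generations: int
    ) -> dict[str, float]:
        """Per-class per-base rates given the genome's A:T vs G:C content."""
        out = {}
        for cls, n in self.items():
            denom = genome_at_bases if cls.startswith("A:T") else genome_gc_bases
            out[cls] = n / (denom * n_generations)
        return out


def mutation_spectrum(sbs: list[Variant]) -> SpectrumTable:
    table = SpectrumTable({c: 0 for c in SPECTRUM_CLASSES})
    for v in sbs:
        if v.kind is not VariantKind.SBS:
            raise ValueError(f"non-SBS variant in spectrum input: {v}")
        table[_spectrum_class(v.ref, v.alt)] += 1
    return table


def tstv_ratio(sbs: list[Variant]) -> float | None:
    """Transitions (A<->G, C<->T) over transversions; None when no
    transversions are present (small sets can hit this)."""
    ts = tv = 0
    for v in sbs:
        if v.kind is not VariantKind.SBS:
            raise ValueError(f"non-SBS variant in Ts/Tv input: {v}")
        ref, alt = v.ref.upper(), v.alt.upper()
        if ref not in _COMP or alt not in _COMP or ref == alt:
            raise ValueError(f"invalid substitution allele pair in {v}")
        if (ref, alt) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ts / tv


def indel_sbs_ratio(n_indel: int, n_sbs: int) -> tuple[float, float | None]:
    """(InDels per substitution, substitutions per InDel); the second is
    None when no InDels were observed."""
    if n_sbs <= 0:
        raise ValueError("n_sbs must be positive")
    ratio = n_indel / n_sbs
    per = (n_sbs / n_indel) if n_indel > 0 else None
    return ratio, per
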