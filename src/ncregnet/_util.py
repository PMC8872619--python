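"""Small shared helpers: rounding and identifier normalisation."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

_MIRNA_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-(?=(mir|let)\b|mir-|let-|miR)", re.IGNORECASE)
_MIRNA_TOKEN = re.compile(r"(mir|let)", re.IGNORECASE)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Python's built-in :func:`round` uses banker's rounding; reported
    percentages here follow the half-away-from-zero convention instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def truncate_percent(x: float) -> int:
    """Whole-percent display: truncate toward zero (26.2 -> 26)."""
    return int(x)


def normalize_gene(symbol: str) -> str:
    """Case-insensitive gene-symbol key."""
    return symbol.strip().upper()


def gene_alias_tokens(symbol: str) -> list[str]:
    """Split slash-joined aliases ("LINC00086/SMIM10L2A") into keys."""
    return [normalize_gene(tok) for tok in symbol.split("/") if tok.strip()]


def normalize_mirna(name: str) -> str:
    """miRNA name key: strip the species prefix (hsa-, mmu-, ...) and
    lowercase, so "hsa-miR-335-3p" and "miR-335-3p" reconcile."""
    return _MIRNA_SPECIES_PREFIX.sub("", name.strip()).lower()


def looks_like_mirna(name: str) -> bool:
    """Heuristic class guess used only by the synthetic generator to
    assign planted hubs to a table."""
    return bool(_MIRNA_TOKEN.search(name))
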