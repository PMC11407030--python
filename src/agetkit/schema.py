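"""Channel schema shared by every pipeline stage.

The model family is fixed: three T-box genes whose mRNA dynamics are
simulated, and two signalling inputs (Wnt and FGF activity) that drive them
but are never themselves modelled.  Every array in the package that carries
per-channel values uses this ordering.
"""

from __future__ import annotations

GENES: tuple[str, ...] = ("tbxta", "tbx16", "tbx6")
SIGNALS: tuple[str, ...] = ("wnt", "fgf")
CHANNELS: tuple[str, ...] = GENES + SIGNALS

N_GENES = len(GENES)
N_SIGNALS = len(SIGNALS)
N_CHANNELS = len(CHANNELS)


class SchemaError(ValueError):
    """An unknown channel name or a shape that violates the channel schema."""


def gene_index(name: str) -> int:
    try:
        return GENES.index(name.lower())
    except ValueError:
        raise SchemaError(f"unknown gene {name!r}; expected one of {GENES}") from None


def signal_index(name: str) -> int:
    try:
        return SIGNALS.index(name.lower())
    except ValueError:
        raise SchemaError(
            f"unknown signal {name!r}; expected one of {SIGNALS}"
        ) from None


def channel_index(name: str) -> int:
    try:
        return CHANNELS.index(name.lower())
    except ValueError:
        raise SchemaError(
            f"unknown channel {name!r}; expected one of {CHANNELS}"
        ) from None
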