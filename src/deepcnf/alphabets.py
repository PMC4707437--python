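"""Label and amino-acid alphabets.

Secondary structure comes in two granularities: the 8-state DSSP alphabet
(three kinds of helix, two of strand, three of coil) and the coarser 3-state
helix/strand/coil alphabet used for Q3 scoring.  Both orderings are frozen
constants: serialized models and one-hot encodings depend on them.
"""

from __future__ import annotations

# 8-state DSSP alphabet, grouped helix / strand / coil:
#   H alpha helix, G 3-10 helix, I pi helix,
#   E extended strand, B beta bridge,
#   T turn, S high-curvature loop, L irregular loop.
SS8_ALPHABET = "HGIEBTSL"
SS3_ALPHABET = "HEC"

_SS8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "L": "C",
}

SS8_INDEX = {s: i for i, s in enumerate(SS8_ALPHABET)}
SS3_INDEX = {s: i for i, s in enumerate(SS3_ALPHABET)}

# 20 standard residues in alphabetical one-letter order, then 'X' for anything
# non-standard.  The 21-way one-hot block and the PSSM column remapping both
# use this ordering.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_UNKNOWN = "X"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

# Coil symbols some DSSP dialects emit instead of 'L'.
_COIL_ALIASES = {" ": "L", "-": "L", "C": "L"}


class InvalidLabelError(ValueError):
    """A secondary-structure symbol outside the known alphabet."""


def map_ss8_to_ss3(label: str) -> str:
    """Map one 8-state DSSP symbol to its 3-state class (H/E/C)."""
    try:
        return _SS8_TO_SS3[label]
    except KeyError:
        raise InvalidLabelError(f"not an 8-state SS symbol: {label!r}") from None


def ss8_string_to_ss3(labels: str) -> str:
    """Map a whole 8-state label string to 3-state."""
    return "".join(map_ss8_to_ss3(s) for s in labels)


def normalize_ss8(labels: str) -> str:
    """Normalize a raw DSSP-derived label string to the strict 8-state alphabet.

    Blank, '-' and 'C' coil dialects become 'L'; anything else unknown raises.
    """
    out = []
    for s in labels:
        s = _COIL_ALIASES.get(s, s)
        if s not in SS8_INDEX:
            raise InvalidLabelError(f"not an 8-state SS symbol: {s!r}")
        out.append(s)
    return "".join(out)


def ss_to_indices(labels: str, alphabet: str) -> list[int]:
    """Encode a label string as integer indices into *alphabet*."""
    index = {s: i for i, s in enumerate(alphabet)}
    try:
        return [index[s] for s in labels]
    except KeyError as exc:
        raise InvalidLabelError(f"symbol {exc.args[0]!r} not in alphabet {alphabet!r}") from None


def indices_to_ss(indices, alphabet: str) -> str:
    """Decode integer label indices back into a string."""
    return "".join(alphabet[int(i)] for i in indices)
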