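"""Feed-forward loop (FFL) topologies.

An FFL consists of a signal protein X regulating a target gene G_Z both
directly and indirectly through an intermediate regulator Y.  Each of the
three edges (X->Y, X->Z, Y->Z) is either activating (+1) or inhibiting (-1),
giving eight distinct sign patterns.  A motif is *coherent* when the sign of
the direct X->Z edge equals the sign product of the indirect X->Y->Z path,
and *incoherent* otherwise; the conventional names are C1-C4 and I1-I4.
"""

from __future__ import annotations

from dataclasses import dataclass

MOTIF_IDS = ("C1", "C2", "C3", "C4", "I1", "I2", "I3", "I4")

ACTIVATION = +1
INHIBITION = -1


@dataclass(frozen=True)
class MotifTopology:
    """Sign pattern of one FFL.

    Parameters
    ----------
    motif_id : str
        One of C1-C4 (coherent) or I1-I4 (incoherent).
    sign_xy, sign_xz, sign_yz : int
        +1 for activation, -1 for inhibition, on the edges X->Y, X->Z
        and Y->Z respectively.
    """

    motif_id: str
    sign_xy: int
    sign_xz: int
    sign_yz: int

    def __post_init__(self) -> None:
        if self.motif_id not in MOTIF_IDS:
            raise ValueError(f"unknown motif id {self.motif_id!r}")
        for s in (self.sign_xy, self.sign_xz, self.sign_yz):
            if s not in (ACTIVATION, INHIBITION):
                raise ValueError("edge signs must be +1 or -1")

    @property
    def coherent(self) -> bool:
        """True when the direct X->Z sign equals the indirect path sign."""
        return self.sign_xz == self.sign_xy * self.sign_yz


# Standard naming (Mangan & Alon convention): C1 is the all-activation loop;
# C2-C4 flip edges while keeping the direct sign equal to the path product,
# I1-I4 oppose it.  Triple order: (sign_xy, sign_xz, sign_yz).
_SIGNS = {
    "C1": (+1, +1, +1),
    "C2": (-1, -1, +1),
    "C3": (+1, -1, -1),
    "C4": (-1, +1, -1),
    "I1": (+1, +1, -1),
    "I2": (-1, -1, -1),
    "I3": (+1, -1, +1),
    "I4": (-1, +1, +1),
}

MOTIFS: dict[str, MotifTopology] = {
    mid: MotifTopology(mid, *signs) for mid, signs in _SIGNS.items()
}


def get_motif(motif_id: str) -> MotifTopology:
    try:
        return MOTIFS[motif_id]
    except KeyError:
        raise ValueError(f"unknown motif id {motif_id!r}") from None
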