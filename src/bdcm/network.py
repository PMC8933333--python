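"""Network structure masks and parameter containers for the generative model.

The default six-node attention network comprises the intraparietal sulcus
(IPS), frontal eye fields (FEF), and temporoparietal junction (TPJ),
bilaterally.  Fixed connections (A) are complete within each hemisphere and
between homologous regions; all regions receive the driving target input
(C); modulation by invalid trials (B) is bidirectional among IPS and TPJ
both within and across hemispheres, but only unidirectional *into* FEF —
no feedback or interhemispheric modulations originate from FEF.

Matrices are target-row, source-column.  The self-connections on the
diagonal of A are parameterized as ``-0.5 * exp(latent)`` so that they are
negative for every latent value, keeping the node dynamics dissipative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_REGIONS",
    "NetworkStructure",
    "HemodynamicParams",
    "BDCMParams",
    "default_posner_structure",
]

DEFAULT_REGIONS = ("IPS-L", "IPS-R", "FEF-L", "FEF-R", "TPJ-L", "TPJ-R")


def _hemisphere(label: str) -> str:
    return label.rsplit("-", 1)[-1]


def _area(label: str) -> str:
    return label.rsplit("-", 1)[0]


@dataclass(eq=False)
class NetworkStructure:
    """Allowed connections and input routes (boolean masks).

    ``A_mask``/``B_masks`` rows are targets, columns sources; ``C_mask`` is
    regions x inputs; ``Ar_mask`` flags the output regions whose neural
    states feed the behavioral response state; ``Br_masks``/``Cr_mask``
    gate modulatory and direct input effects on the behavioral state.
    """

    region_labels: tuple[str, ...]
    A_mask: np.ndarray  # R x R bool
    B_masks: np.ndarray  # J x R x R bool
    C_mask: np.ndarray  # R x J bool
    Ar_mask: np.ndarray  # R bool
    Br_masks: np.ndarray  # J x R bool
    Cr_mask: np.ndarray  # J bool

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_inputs(self) -> int:
        return self.B_masks.shape[0]

    def region_index(self, label: str) -> int:
        try:
            return self.region_labels.index(label)
        except ValueError:
            raise ValueError(
                f"unknown region {label!r}; known: {list(self.region_labels)}"
            ) from None

    def with_output_regions(self, labels: Sequence[str]) -> "NetworkStructure":
        """Copy of this structure with ``Ar_mask`` set to the given regions."""
        mask = np.zeros(self.n_regions, dtype=bool)
        for lab in labels:
            mask[self.region_index(lab)] = True
        return replace(self, Ar_mask=mask)

    def with_n_inputs(self, n_inputs: int) -> "NetworkStructure":
        """Copy with input-indexed masks grown (new inputs start inactive)."""
        j0 = self.n_inputs
        if n_inputs < j0:
            raise ValueError("cannot shrink the number of inputs")
        b = np.zeros((n_inputs, self.n_regions, self.n_regions), dtype=bool)
        b[:j0] = self.B_masks
        c = np.zeros((self.n_regions, n_inputs), dtype=bool)
        c[:, :j0] = self.C_mask
        br = np.zeros((n_inputs, self.n_regions), dtype=bool)
        br[:j0] = self.Br_masks
        cr = np.zeros(n_inputs, dtype=bool)
        cr[:j0] = self.Cr_mask
        return replace(self, B_masks=b, C_mask=c, Br_masks=br, Cr_mask=cr)


def default_posner_structure(
    region_labels: Sequence[str] = DEFAULT_REGIONS,
    output_regions: Sequence[str] = ("IPS-L", "IPS-R"),
    n_inputs: int = 2,
) -> NetworkStructure:
    """The six-region attention-network structure described above."""
    labels = tuple(region_labels)
    r = len(labels)
    a = np.zeros((r, r), dtype=bool)
    for i in range(r):
        for j in range(r):
            if i == j:
                a[i, j] = True  # self-connections
            elif _hemisphere(labels[i]) == _hemisphere(labels[j]):
                a[i, j] = True  # complete within hemisphere
            elif _area(labels[i]) == _area(labels[j]):
                a[i, j] = True  # homologous interhemispheric

    b = np.zeros((n_inputs, r, r), dtype=bool)
    if n_inputs >= 2:
        modulated = [lab for lab in labels if _area(lab) != "FEF"]
        for src in modulated:
            for tgt in modulated:
                i, j = labels.index(tgt), labels.index(src)
                if i != j and a[i, j]:
                    b[1, i, j] = True  # bidirectional among IPS and TPJ
        for tgt in labels:
            if _area(tgt) != "FEF":
                continue
            for src in modulated:
                i, j = labels.index(tgt), labels.index(src)
                if a[i, j]:
                    b[1, i, j] = True  # into FEF only, never from it

    c = np.zeros((r, n_inputs), dtype=bool)
    c[:, 0] = True  # all regions receive the driving target input

    structure = NetworkStructure(
        region_labels=labels,
        A_mask=a,
        B_masks=b,
        C_mask=c,
        Ar_mask=np.zeros(r, dtype=bool),
        Br_masks=np.zeros((n_inputs, r), dtype=bool),
        Cr_mask=np.zeros(n_inputs, dtype=bool),
    )
    return structure.with_output_regions(output_regions)


@dataclass
class HemodynamicParams:
    """Balloon/Windkessel constants (shared across regions).

    Units: ``kappa`` (vasodilatory signal decay) and ``gamma``
    (flow autoregulation) in 1/s, ``tau`` (mean transit time) in s;
    ``alpha`` is Grubb's vessel stiffness exponent, ``e0`` the resting
    oxygen extraction fraction, and ``v0`` the resting venous volume
    fraction expressed in signal-percent units.
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    e0: float = 0.4
    v0: float = 4.0


@dataclass
class BDCMParams:
    """All parameters of the joint BOLD + behavior generative model.

    ``A`` (with negative self-connections), ``B`` (one matrix per input),
    and ``C`` govern the neural dynamics; ``phi`` the hemodynamics;
    ``ar``/``br``/``cr`` (the behavioral evolution weights), ``decay``
    (the leak of the response state), and ``rho`` (the readout bias) govern
    behavior.  Entries outside the structure masks must be exactly zero.
    """

    A: np.ndarray  # R x R
    B: np.ndarray  # J x R x R
    C: np.ndarray  # R x J
    ar: np.ndarray  # R
    br: np.ndarray  # J x R
    cr: np.ndarray  # J
    decay: float = 0.0
    rho: float = 0.0
    phi: HemodynamicParams = field(default_factory=HemodynamicParams)

    @staticmethod
    def zeros(structure: NetworkStructure) -> "BDCMParams":
        r, j = structure.n_regions, structure.n_inputs
        return BDCMParams(
            A=np.zeros((r, r)),
            B=np.zeros((j, r, r)),
            C=np.zeros((r, j)),
            ar=np.zeros(r),
            br=np.zeros((j, r)),
            cr=np.zeros(j),
        )

    def validate(self, structure: NetworkStructure) -> None:
        """Raise if any parameter value escapes its structure mask."""
        checks = [
            (self.A * ~structure.A_mask, "A"),
            (self.B * ~structure.B_masks, "B"),
            (self.C * ~structure.C_mask, "C"),
            (self.ar * ~structure.Ar_mask, "ar"),
            (self.br * ~structure.Br_masks, "br"),
            (self.cr * ~structure.Cr_mask, "cr"),
        ]
        for leaked, name in checks:
            if np.any(leaked != 0):
                raise ValueError(f"nonzero {name} entries outside the structure mask")

    def copy(self) -> "BDCMParams":
        return BDCMParams(
            A=self.A.copy(),
            B=self.B.copy(),
            C=self.C.copy(),
            ar=self.ar.copy(),
            br=self.br.copy(),
            cr=self.cr.copy(),
            decay=self.decay,
            rho=self.rho,
            phi=replace(self.phi),
        )
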