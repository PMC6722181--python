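"""Two-arm decision-tree model: chance nodes and effectiveness.

Each arm of the tree is one imaging modality (amino-acid PET or
conventional MRI).  The first branch is the modality's call
(responder / non-responder); the second branch is the clinical truth
conditional on the call.  Six chance probabilities parameterise the
tree:

======  ===========================================================
node    meaning
======  ===========================================================
N1      P(PET calls responder)
N2      P(MRI calls responder)
N3      P(true responder | PET responder)
N4      P(true non-responder | PET non-responder)
N5      P(true responder | MRI responder)
N6      P(true non-responder | MRI non-responder)
======  ===========================================================

All probabilities are estimated on an *available-case* basis per
modality: a patient contributes to the PET arm only when both PET
scans exist, and to the MRI arm only when both MRI scans exist.  In
particular the non-responder identification rate conditions on true
non-responders *with that modality available* — the natural estimand
when each arm is evaluated on its own evaluable patients.

The headline effectiveness measure is the non-responder identification
rate: among true clinical non-responders, the fraction the modality
flags as non-responders (a sensitivity for the non-response state).
In node terms, with R the responder-call probability, p the positive
predictive fraction of responder calls and q of non-responder calls:

    nr_identification = (1-R)·q / [ (1-R)·q + R·(1-p) ]

where the denominator is the total probability of being a true
non-responder and the numerator the probability of being a correctly
flagged one.  Diagnostic accuracy, the secondary measure, is the
probability of a concordant call: R·p + (1-R)·q.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from fractions import Fraction
from pathlib import Path

from .classify import ClassifiedPatient, Endpoint, ResponseStatus

__all__ = [
    "NodeCount",
    "ChanceNodeSet",
    "TreeEffectiveness",
    "UndefinedNodeError",
    "UndefinedEffectivenessError",
    "estimate_chance_nodes",
    "event_probabilities",
    "effectiveness",
    "effectiveness_by_count",
]


class UndefinedNodeError(ValueError):
    """A chance node's conditioning stratum is empty."""


class UndefinedEffectivenessError(ValueError):
    """The true-non-responder probability is zero for a modality."""


@dataclass(frozen=True)
class NodeCount:
    """A probability together with the counts it was estimated from."""

    numerator: int
    denominator: int

    @property
    def probability(self) -> float:
        return self.numerator / self.denominator

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)


@dataclass(frozen=True)
class ChanceNodeSet:
    """The six chance-node estimates for one clinical endpoint."""

    endpoint: Endpoint
    n1: NodeCount  # P(PET call = R)
    n2: NodeCount  # P(MRI call = R)
    n3: NodeCount  # P(true R | PET R)
    n4: NodeCount  # P(true NR | PET NR)
    n5: NodeCount  # P(true R | MRI R)
    n6: NodeCount  # P(true NR | MRI NR)

    def probabilities(self) -> dict[str, float]:
        """Node probabilities keyed ``n1`` … ``n6``."""
        return {k: getattr(self, k).probability for k in ("n1", "n2", "n3", "n4", "n5", "n6")}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "endpoint": self.endpoint,
            **{
                k: {
                    "probability": getattr(self, k).probability,
                    "numerator": getattr(self, k).numerator,
                    "denominator": getattr(self, k).denominator,
                }
                for k in ("n1", "n2", "n3", "n4", "n5", "n6")
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


@dataclass(frozen=True)
class TreeEffectiveness:
    """Per-modality effectiveness and the PET-minus-MRI increments."""

    endpoint: Endpoint
    pet_nr_identification: float
    mri_nr_identification: float
    delta_nr: float
    pet_accuracy: float
    mri_accuracy: float
    delta_accuracy: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def _node(numerator: int, denominator: int, name: str) -> NodeCount:
    if denominator == 0:
        raise UndefinedNodeError(f"chance node {name} undefined: empty stratum")
    return NodeCount(numerator, denominator)


def estimate_chance_nodes(
    classified: tuple[ClassifiedPatient, ...] | list[ClassifiedPatient],
    endpoint: Endpoint,
) -> ChanceNodeSet:
    """Estimate N1–N6 from a classified cohort, available-case per modality."""
    R, NR = ResponseStatus.RESPONDER, ResponseStatus.NON_RESPONDER

    pet_avail = [c for c in classified if c.pet.available]
    mri_avail = [c for c in classified if c.mri.available]
    if not pet_avail or not mri_avail:
        raise UndefinedNodeError(
            "need at least one PET-available and one MRI-available patient"
        )

    pet_r = [c for c in pet_avail if c.pet is R]
    pet_nr = [c for c in pet_avail if c.pet is NR]
    mri_r = [c for c in mri_avail if c.mri is R]
    mri_nr = [c for c in mri_avail if c.mri is NR]

    def truth(c: ClassifiedPatient) -> ResponseStatus:
        return c.clinical(endpoint)

    return ChanceNodeSet(
        endpoint=endpoint,
        n1=_node(len(pet_r), len(pet_avail), "N1"),
        n2=_node(len(mri_r), len(mri_avail), "N2"),
        n3=_node(sum(truth(c) is R for c in pet_r), len(pet_r), "N3"),
        n4=_node(sum(truth(c) is NR for c in pet_nr), len(pet_nr), "N4"),
        n5=_node(sum(truth(c) is R for c in mri_r), len(mri_r), "N5"),
        n6=_node(sum(truth(c) is NR for c in mri_nr), len(mri_nr), "N6"),
    )


def event_probabilities(
    nodes: ChanceNodeSet | dict[str, float]
) -> dict[str, dict[str, float]]:
    """The four joint call/truth outcome probabilities per modality.

    For each modality with responder-call probability R and conditional
    truth probabilities p (given call R) and q (given call NR), the leaf
    probabilities are the products along each path of the tree; they sum
    to 1 per modality.
    """
    probs = nodes.probabilities() if isinstance(nodes, ChanceNodeSet) else nodes
    out: dict[str, dict[str, float]] = {}
    for modality, (rk, pk, qk) in {
        "pet": ("n1", "n3", "n4"),
        "mri": ("n2", "n5", "n6"),
    }.items():
        R, p, q = probs[rk], probs[pk], probs[qk]
        out[modality] = {
            "call_r_true_r": R * p,
            "call_r_true_nr": R * (1.0 - p),
            "call_nr_true_nr": (1.0 - R) * q,
            "call_nr_true_r": (1.0 - R) * (1.0 - q),
        }
    return out


def nr_identification_rate(R, p, q):
    """Sensitivity for the non-response state implied by (R, p, q).

    ``(1-R)·q`` is the probability of a correctly flagged true
    non-responder, ``R·(1-p)`` of a missed one.  Works with floats or
    :class:`~fractions.Fraction` values alike.
    """
    true_nr = (1 - R) * q + R * (1 - p)
    if true_nr <= 0:
        raise UndefinedEffectivenessError(
            "true-non-responder probability is zero; identification rate undefined"
        )
    return (1 - R) * q / true_nr


def effectiveness(nodes: ChanceNodeSet | dict[str, float],
                  endpoint: Endpoint | None = None) -> TreeEffectiveness:
    """Per-modality non-responder identification rate and accuracy from nodes.

    Accepts either an estimated :class:`ChanceNodeSet` or a plain
    ``{"n1": …, …, "n6": …}`` mapping (used by the sensitivity analyses,
    which perturb node values directly).  For a :class:`ChanceNodeSet`
    the arithmetic is done on the exact count fractions, so the result
    matches :func:`effectiveness_by_count` bit for bit.
    """
    probs: dict[str, float | Fraction]
    if isinstance(nodes, ChanceNodeSet):
        probs = {k: getattr(nodes, k).fraction for k in ("n1", "n2", "n3", "n4", "n5", "n6")}
        endpoint = nodes.endpoint
    else:
        probs = dict(nodes)
        if endpoint is None:
            raise ValueError("endpoint required when passing raw node probabilities")

    pet_nr = float(nr_identification_rate(probs["n1"], probs["n3"], probs["n4"]))
    mri_nr = float(nr_identification_rate(probs["n2"], probs["n5"], probs["n6"]))
    pet_acc = float(probs["n1"] * probs["n3"] + (1 - probs["n1"]) * probs["n4"])
    mri_acc = float(probs["n2"] * probs["n5"] + (1 - probs["n2"]) * probs["n6"])
    return TreeEffectiveness(
        endpoint=endpoint,
        pet_nr_identification=pet_nr,
        mri_nr_identification=mri_nr,
        delta_nr=pet_nr - mri_nr,
        pet_accuracy=pet_acc,
        mri_accuracy=mri_acc,
        delta_accuracy=pet_acc - mri_acc,
    )


def effectiveness_by_count(
    classified: tuple[ClassifiedPatient, ...] | list[ClassifiedPatient],
    endpoint: Endpoint,
) -> TreeEffectiveness:
    """Effectiveness by direct patient counting (independent of the tree).

    Computes the same quantities as :func:`effectiveness` without going
    through node probabilities: the identification rate is the count of
    correctly flagged true non-responders over the count of true
    non-responders among patients with the modality available, and
    accuracy is the count of concordant calls over available patients.
    Algebraically identical to the node route; kept as a cross-check.
    """
    R, NR = ResponseStatus.RESPONDER, ResponseStatus.NON_RESPONDER

    def rates(modality: str) -> tuple[float, float]:
        avail = [c for c in classified if getattr(c, modality).available]
        if not avail:
            raise UndefinedNodeError(f"no {modality.upper()}-available patients")
        true_nr = [c for c in avail if c.clinical(endpoint) is NR]
        if not true_nr:
            raise UndefinedEffectivenessError(
                f"no true non-responders among {modality.upper()}-available patients"
            )
        flagged = sum(getattr(c, modality) is NR for c in true_nr)
        concordant = sum(
            (getattr(c, modality) is R and c.clinical(endpoint) is R)
            or (getattr(c, modality) is NR and c.clinical(endpoint) is NR)
            for c in avail
        )
        return flagged / len(true_nr), concordant / len(avail)

    pet_nr, pet_acc = rates("pet")
    mri_nr, mri_acc = rates("mri")
    return TreeEffectiveness(
        endpoint=endpoint,
        pet_nr_identification=pet_nr,
        mri_nr_identification=mri_nr,
        delta_nr=pet_nr - mri_nr,
        pet_accuracy=pet_acc,
        mri_accuracy=mri_acc,
        delta_accuracy=pet_acc - mri_acc,
    )
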