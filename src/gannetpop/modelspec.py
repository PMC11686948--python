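"""Candidate model structures for the covariate-selection exercise.

A :class:`ModelSpec` names which climate covariates enter the fecundity
and recruitment linear predictors, and at which polynomial order (1 =
linear, 2 = downward parabola).  Model ids follow the published naming
scheme: ``m<k>.<digits>`` where digits index covariates in the order
SST=1, SLM=2, nsAT=3, nsWS=4, prec=5, fecundity slots first and the
recruitment slot last, with ``^2`` marking a quadratic term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import COVARIATES

_COV_DIGIT = {c: i + 1 for i, c in enumerate(COVARIATES)}


@dataclass(frozen=True)
class ModelSpec:
    """Terms of the two linear predictors.

    ``fecundity_terms`` / ``recruitment_terms`` are tuples of
    ``(covariate_name, order)`` with order in {1, 2}.  An order-2 entry
    requires the order-1 entry for the same covariate (parabolas always
    include their linear term).
    """

    id: str
    fecundity_terms: tuple = field(default_factory=tuple)
    recruitment_terms: tuple = field(default_factory=tuple)

    def __post_init__(self):
        for side, terms in (("fecundity", self.fecundity_terms),
                            ("recruitment", self.recruitment_terms)):
            for cov, order in terms:
                if cov not in COVARIATES:
                    raise ValueError(f"unknown covariate {cov!r} in {side} terms")
                if order not in (1, 2):
                    raise ValueError(f"polynomial order must be 1 or 2, got {order}")
            quads = {c for c, o in terms if o == 2}
            lins = {c for c, o in terms if o == 1}
            if not quads <= lins:
                raise ValueError(
                    f"{side}: quadratic terms {sorted(quads - lins)} lack their linear term"
                )

    def covariates(self, side: str) -> list:
        """Linear covariates of one predictor, in canonical order, with quad flags."""
        terms = self.fecundity_terms if side == "fecundity" else self.recruitment_terms
        quads = {c for c, o in terms if o == 2}
        lins = [c for c, o in terms if o == 1]
        lins.sort(key=COVARIATES.index)
        return [(c, c in quads) for c in lins]

    @property
    def n_parameters(self) -> int:
        """Number of covariate coefficients (intercepts excluded)."""
        return len(self.fecundity_terms) + len(self.recruitment_terms)


def _spec(fec, rec) -> ModelSpec:
    """Build a ModelSpec with its systematic id from term lists."""
    n = len(fec) + len(rec)
    fdig = "".join(
        f"{_COV_DIGIT[c]}^2" if o == 2 else str(_COV_DIGIT[c]) for c, o in _expand(fec)
    )
    rdig = "".join(
        f"{_COV_DIGIT[c]}^2" if o == 2 else str(_COV_DIGIT[c]) for c, o in _expand(rec)
    )
    fdig = fdig or "0"
    rdig = rdig or "0"
    return ModelSpec(id=f"m{n_label(fec, rec)}.{fdig}{rdig}",
                     fecundity_terms=tuple(fec), recruitment_terms=tuple(rec))


def _expand(terms):
    """Collapse (cov,1)+(cov,2) pairs into a single labelled slot."""
    quads = {c for c, o in terms if o == 2}
    out = []
    for c, o in terms:
        if o == 1:
            out.append((c, 2 if c in quads else 1))
    return out


def n_label(fec, rec) -> int:
    """Covariate-slot count used in the model id (quadratics share a slot)."""
    return len({c for c, _ in fec}) + len({c for c, _ in rec})


NULL_MODEL = ModelSpec(id="m0.00")


def enumerate_models() -> list:
    """The 47 candidate structures of the selection exercise.

    Null; five single-covariate fecundity models; five single-covariate
    recruitment models; the 25 one-covariate-each pairs; three quadratic
    extensions of the best pair (fecundity nsAT + recruitment SST); and
    eight two-covariate fecundity models (a second covariate next to a
    linear or quadratic nsAT term, recruitment SST throughout).
    """
    models = [NULL_MODEL]
    for c in COVARIATES:
        models.append(_spec([(c, 1)], []))
    for c in COVARIATES:
        models.append(_spec([], [(c, 1)]))
    for cf in COVARIATES:
        for cr in COVARIATES:
            models.append(_spec([(cf, 1)], [(cr, 1)]))
    # quadratic extensions of the best single-covariate pair
    models.append(_spec([("nsAT", 1)], [("SST", 1), ("SST", 2)]))
    models.append(_spec([("nsAT", 1), ("nsAT", 2)], [("SST", 1)]))
    models.append(_spec([("nsAT", 1), ("nsAT", 2)], [("SST", 1), ("SST", 2)]))
    # second fecundity covariate next to linear / quadratic nsAT
    for extra in ("SST", "SLM", "nsWS", "prec"):
        models.append(_spec([("nsAT", 1), (extra, 1)], [("SST", 1)]))
    for extra in ("SST", "SLM", "nsWS", "prec"):
        models.append(_spec([("nsAT", 1), ("nsAT", 2), (extra, 1)], [("SST", 1)]))
    return models


def _id_digits(fec, rec):  # pragma: no cover - helper kept for doc clarity
    return _spec(fec, rec).id
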