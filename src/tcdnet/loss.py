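"""The object-counting loss: localization + boundary + false-positive terms.

The network output is a per-pixel probability map P.  Three terms turn
box-level supervision into a counting objective:

* localization — pull P toward 1 at every annotated object center, weighted
  by the number of objects in the image (lambda_L = sum(T_L));
* boundary — push P toward 0 on the box-derived boundary pixels, weighted by
  lambda_B = max(n_objects - 1, 0), so crowded images are constrained harder
  and a single isolated object is unconstrained;
* false positive — threshold P, label connected components, and push toward
  0 every pixel of a component that contains no ground-truth center.

All terms are computed from logits with log-sigmoid stability:
-log sigmoid(z) = softplus(-z) and -log(1 - sigmoid(z)) = softplus(z).
Component mining runs on detached probabilities; gradients flow only through
the per-pixel log terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .annotations import BoundaryMatrix, CenterMatrix
from .model import ProbabilityMap
from .postprocess import label_components


@dataclass
class LossBreakdown:
    localization: float
    boundary: float
    false_positive: float
    total_tensor: Tensor | None = None

    @property
    def total(self) -> float:
        return self.localization + self.boundary + self.false_positive


def _logits_tensor(p: ProbabilityMap) -> Tensor:
    if p.logits_tensor is not None:
        return p.logits_tensor
    return Tensor(p.logits)


def _masked_softplus_sum(logits: Tensor, mask: np.ndarray, negate: bool) -> Tensor | None:
    """sum over mask of softplus(±z); None when the mask is empty."""
    if not mask.any():
        return None
    sel = logits[mask]
    if negate:
        sel = sel * -1.0
    return T.tsum(T.softplus(sel))


def localization_loss(p: ProbabilityMap, t_l: CenterMatrix) -> tuple[float, Tensor | None]:
    """-lambda_L * sum over centers of log(P_i), lambda_L = sum(T_L)."""
    lam = t_l.n_centers
    if lam == 0:
        return 0.0, None
    term = _masked_softplus_sum(_logits_tensor(p), t_l.values.astype(bool), negate=True)
    term = term * float(lam)
    return term.item(), term


def boundary_loss(p: ProbabilityMap, t_b: BoundaryMatrix, n_objects: int,
                  lambda_mode: str = "count_minus_one") -> tuple[float, Tensor | None]:
    """-lambda_B * sum over boundary pixels of log(1 - P_i).

    lambda_mode "count_minus_one" (default): lambda_B = max(n - 1, 0);
    "inverse_count": lambda_B = 1 / n — the alternative reading of the
    weight, kept as a switch.
    """
    if lambda_mode == "count_minus_one":
        lam = max(n_objects - 1, 0)
    elif lambda_mode == "inverse_count":
        lam = 1.0 / n_objects if n_objects else 0.0
    else:
        raise ValueError(f"unknown lambda_mode {lambda_mode!r}")
    if lam == 0:
        return 0.0, None
    term = _masked_softplus_sum(_logits_tensor(p), t_b.values.astype(bool), negate=False)
    if term is None:
        return 0.0, None
    term = term * float(lam)
    return term.item(), term


def false_positive_region_mask(values: np.ndarray, t_l: CenterMatrix,
                               threshold: float = 0.5,
                               connectivity: int = 4) -> np.ndarray:
    """Boolean mask of pixels in thresholded components without any center."""
    mask = values >= threshold
    labels = label_components(mask, connectivity=connectivity)
    if labels.n_labels == 0:
        return np.zeros_like(mask)
    centers = t_l.values.astype(bool)
    has_center = np.zeros(labels.n_labels + 1, dtype=bool)
    has_center[np.unique(labels.values[centers])] = True
    has_center[0] = True   # background is never a false positive region
    return ~has_center[labels.values]


def false_positive_loss(p: ProbabilityMap, t_l: CenterMatrix,
                        threshold: float = 0.5,
                        connectivity: int = 4) -> tuple[float, Tensor | None]:
    """-sum over false-positive-region pixels of log(1 - P_i)."""
    fp_mask = false_positive_region_mask(p.values, t_l, threshold, connectivity)
    term = _masked_softplus_sum(_logits_tensor(p), fp_mask, negate=False)
    if term is None:
        return 0.0, None
    return term.item(), term


def oc_loss(p: ProbabilityMap, t_l: CenterMatrix, t_b: BoundaryMatrix,
            fp_threshold: float = 0.5, connectivity: int = 4,
            lambda_mode: str = "count_minus_one",
            terms: tuple[str, ...] = ("localization", "boundary", "false_positive"),
            ) -> LossBreakdown:
    """The full counting loss; ``terms`` selects active components (for
    ablations).  The returned breakdown carries the differentiable total when
    the probability map came from the network."""
    n = t_l.n_centers
    vals = {"localization": 0.0, "boundary": 0.0, "false_positive": 0.0}
    tensors = []
    if "localization" in terms:
        vals["localization"], t = localization_loss(p, t_l)
        if t is not None:
            tensors.append(t)
    if "boundary" in terms:
        vals["boundary"], t = boundary_loss(p, t_b, n, lambda_mode)
        if t is not None:
            tensors.append(t)
    if "false_positive" in terms:
        vals["false_positive"], t = false_positive_loss(p, t_l, fp_threshold, connectivity)
        if t is not None:
            tensors.append(t)
    total_t = None
    if tensors:
        total_t = tensors[0]
        for t in tensors[1:]:
            total_t = total_t + t
    return LossBreakdown(vals["localization"], vals["boundary"],
                         vals["false_positive"], total_tensor=total_t)
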