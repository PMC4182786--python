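"""Model-based probe filtering.

Before inference, genes that are never expressed (array background) or
pinned at the scanner ceiling (saturated) are removed.  Each gene is
summarised by the mean and standard deviation of its log2 profile pooled
over all samples of both conditions, and a finite Gaussian mixture is fit in
that (mean, sd) plane.  The component with the lowest mean is labelled
non-expressed; components sitting near the top of the log2 range with
near-zero spread are labelled saturated; everything else is expressed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import NotFittedError
from sklearn.mixture import GaussianMixture

from .expression import ExpressionMatrix

__all__ = ["ProbeFilterResult", "FilterFitError", "filter_probes"]

FLAGS = ("expressed", "non_expressed", "saturated")


class FilterFitError(RuntimeError):
    """Mixture fit failure on degenerate data, with diagnostics attached."""


@dataclass(frozen=True)
class ProbeFilterResult:
    """Per-gene flags plus the fitted mixture.

    ``flags`` maps every gene to exactly one of expressed / non_expressed /
    saturated; ``posterior`` is the responsibility of the gene's assigned
    component.  ``component_means``/``component_sds``/``weights`` describe the
    mixture in (mean, sd) feature space.
    """

    flags: pd.Series
    posterior: pd.Series
    component_means: np.ndarray
    component_sds: np.ndarray
    weights: np.ndarray

    def kept_genes(self) -> list[str]:
        return list(self.flags.index[self.flags == "expressed"])

    def counts(self) -> dict[str, int]:
        return {f: int((self.flags == f).sum()) for f in FLAGS}


def filter_probes(
    expr: ExpressionMatrix | pd.DataFrame,
    n_components: int = 3,
    seed: int = 0,
    saturated_mean_min: float = 12.5,
    saturated_sd_max: float = 0.2,
) -> ProbeFilterResult:
    """Flag non-expressed and saturated genes with a Gaussian mixture.

    The mixture is fit on per-gene (mean, sd) summaries pooled over all
    samples.  Assignment rules: the component with the lowest mean feature is
    non_expressed; a component whose mean feature exceeds
    ``saturated_mean_min`` with average spread below ``saturated_sd_max`` is
    saturated; the rest are expressed.  A sanity guard keeps any gene whose
    mean is above the global median while its sd is above the 10th
    percentile, whatever its component.  Deterministic for a fixed seed.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[0] < 10:
        raise ValueError("probe filtering needs at least 10 genes")
    feats = np.column_stack(
        [values.mean(axis=1).to_numpy(), values.std(axis=1, ddof=1).to_numpy()]
    )
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        n_init=5,
        # covariance floor keeps near-degenerate components (saturated genes
        # pinned at the ceiling) from rejecting their own mild outliers
        reg_covar=1e-4,
        random_state=seed,
    )
    try:
        labels = gm.fit_predict(feats)
    except (ValueError, NotFittedError) as err:
        raise FilterFitError(
            f"mixture fit failed on {values.shape[0]} genes "
            f"(feature ranges: mean {feats[:, 0].min():.2f}-{feats[:, 0].max():.2f}, "
            f"sd {feats[:, 1].min():.3f}-{feats[:, 1].max():.3f}): {err}"
        ) from err
    resp = gm.predict_proba(feats)
    comp_mean = gm.means_[:, 0]
    comp_sd = gm.means_[:, 1]
    flag_of_comp = np.full(n_components, "expressed", dtype=object)
    flag_of_comp[int(np.argmin(comp_mean))] = "non_expressed"
    for c in range(n_components):
        if comp_mean[c] >= saturated_mean_min and comp_sd[c] <= saturated_sd_max:
            flag_of_comp[c] = "saturated"
    flags = pd.Series(
        [flag_of_comp[c] for c in labels], index=values.index, name="flag", dtype=object
    )
    # sanity guard: clearly expressed, variable genes are never flagged as
    # non-expressed (saturated genes sit near zero spread by definition, so
    # the sd percentile is not informative for them)
    mean_med = np.median(feats[:, 0])
    sd_p10 = np.quantile(feats[:, 1], 0.10)
    guard = (feats[:, 0] > mean_med) & (feats[:, 1] > sd_p10)
    flags[guard & (flags == "non_expressed").to_numpy()] = "expressed"
    posterior = pd.Series(
        resp[np.arange(len(labels)), labels], index=values.index, name="posterior"
    )
    return ProbeFilterResult(
        flags=flags,
        posterior=posterior,
        component_means=comp_mean.copy(),
        component_sds=comp_sd.copy(),
        weights=gm.weights_.copy(),
    )
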