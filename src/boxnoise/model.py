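"""Model/results interface to the localization-noise analysis.

:class:`LocalizationNoiseModel` is built from a paired (clean, noisy)
version of the same label set; :meth:`~LocalizationNoiseModel.fit`
matches the boxes, estimates the noise law and returns a
:class:`LocalizationNoiseResults` carrying the estimates (gamma, sigma,
size-binned dispersion and its fitted slope, boundary correlations), a
``summary()`` table, and ``simulate()`` / plotting conveniences.

Example
-------
>>> from boxnoise import (FixtureConfig, generate_annotation_set,
...                       NoiseModel, synthesize, LocalizationNoiseModel)
>>> clean = generate_annotation_set(FixtureConfig(n_images=500, seed=1))
>>> noisy = synthesize(clean, NoiseModel(gamma=0.15, seed=2))
>>> res = LocalizationNoiseModel(clean, noisy).fit()
>>> round(res.gamma, 2)
0.15
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import AnnotationSet
from .matching import BOUNDARIES, NoiseReport, noise_report
from .synthesis import NoiseModel, synthesize
from .voc import read_voc


class LocalizationNoiseModel:
    """Estimate the size-proportional Gaussian noise law from paired labels.

    Parameters
    ----------
    clean, noisy
        Two annotation versions of the same images; the clean one is the
        reference against which boundary errors are measured.
    bin_width, rescale_to, min_bin_count
        Size-binning controls for the dispersion curve: errors are
        rescaled to a square ``rescale_to``-pixel reference image and
        grouped in ``bin_width``-pixel bins; bins with fewer than
        ``min_bin_count`` errors are dropped.
    """

    def __init__(self, clean: AnnotationSet, noisy: AnnotationSet, *,
                 bin_width: float = 64.0, rescale_to: float = 640.0,
                 min_bin_count: int = 10):
        self.clean = clean
        self.noisy = noisy
        self.bin_width = bin_width
        self.rescale_to = rescale_to
        self.min_bin_count = min_bin_count

    @classmethod
    def from_voc_dirs(cls, clean_dir, noisy_dir, **kwargs
                      ) -> "LocalizationNoiseModel":
        """Build the model from two directories of Pascal VOC XML files."""
        return cls(read_voc(clean_dir), read_voc(noisy_dir), **kwargs)

    def fit(self) -> "LocalizationNoiseResults":
        report = noise_report(
            self.clean, self.noisy,
            bin_width=self.bin_width, rescale_to=self.rescale_to,
            min_bin_count=self.min_bin_count,
        )
        return LocalizationNoiseResults(model=self, report=report)


@dataclass
class LocalizationNoiseResults:
    """Fitted noise diagnostics with summary, simulation and plotting."""

    model: LocalizationNoiseModel
    report: NoiseReport

    @property
    def gamma(self) -> float:
        """Root mean square relative boundary error (the noise level)."""
        return self.report.gamma_overall

    @property
    def sigma(self) -> float:
        """Root mean square absolute boundary error in pixels."""
        return self.report.sigma_overall

    @property
    def sigma_slope(self) -> Optional[float]:
        """Through-origin slope of local sigma versus box size (~ gamma)."""
        return self.report.sigma_slope

    @property
    def correlation(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.report.correlation.values,
                             index=BOUNDARIES, columns=BOUNDARIES)
        return frame.mask(~self.report.correlation.defined)

    @property
    def boundary_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gamma": self.report.gamma_per_boundary,
            "mean_relative": self.report.mean_relative_per_boundary,
        }).loc[list(BOUNDARIES)]

    def simulate(self, clean: Optional[AnnotationSet] = None,
                 gamma: Optional[float] = None, seed: int = 0
                 ) -> AnnotationSet:
        """Synthesize a noisy set at the fitted (or given) noise level."""
        clean = clean if clean is not None else self.model.clean
        level = gamma if gamma is not None else self.gamma
        return synthesize(clean, NoiseModel(gamma=level, seed=seed))

    def summary(self) -> str:
        r = self.report
        lines = [
            "Localization noise analysis",
            "=" * 46,
            f"images matched        {r.n_images:>10d}",
            f"box pairs             {r.n_pairs:>10d}",
            f"unmatched clean boxes {r.n_unmatched_clean:>10d}",
            f"boundary errors       {r.n_errors:>10d}",
            f"gamma (RMS relative)  {r.gamma_overall:>10.4f}",
            f"sigma (RMS px)        {r.sigma_overall:>10.2f}",
        ]
        if r.sigma_slope is not None:
            lines.append(f"sigma-size slope      {r.sigma_slope:>10.4f}")
        lines.append("-" * 46)
        lines.append("per boundary            gamma   mean rel.")
        for b in BOUNDARIES:
            lines.append(f"  {b:<18s} {r.gamma_per_boundary[b]:>10.4f}"
                         f" {r.mean_relative_per_boundary[b]:>10.4f}")
        if r.size_class_stats:
            lines.append("-" * 46)
            lines.append("size class          n      mean rel.   std rel.")
            for cls, st in r.size_class_stats.items():
                lines.append(f"  {cls:<10s} {st['n']:>8d} {st['mean']:>12.4f}"
                             f" {st['std']:>10.4f}")
        return "\n".join(lines)

    def plot_binned_sigma(self, ax=None):
        """Scatter of local sigma versus box size with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sizes = [p[0] for p in self.report.binned_sigma]
        sigmas = [p[1] for p in self.report.binned_sigma]
        ax.plot(sizes, sigmas, "o", label="local sigma")
        if self.sigma_slope is not None and sizes:
            xs = np.linspace(0, max(sizes) * 1.05, 50)
            ax.plot(xs, self.sigma_slope * xs, "-",
                    label=f"slope {self.sigma_slope:.3f}")
        ax.set_xlabel(f"box size (px, rescaled to {self.model.rescale_to:g})")
        ax.set_ylabel("local sigma (px)")
        ax.legend()
        return ax

    def plot_histograms(self, ax=None):
        """Relative-error histograms by size class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cls, h in self.report.histograms.items():
            edges = np.asarray(h["edges"])
            centers = 0.5 * (edges[:-1] + edges[1:])
            counts = np.asarray(h["counts"], dtype=float)
            total = counts.sum()
            if total:
                counts = counts / total
            ax.step(centers, counts, where="mid", label=cls)
        ax.set_xlabel("relative boundary error")
        ax.set_ylabel("relative frequency")
        ax.legend()
        return ax
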