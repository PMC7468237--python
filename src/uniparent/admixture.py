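"""Constant-gene-flow model linking origin fractions to per-generation rates.

Under "raw constant gene flow", every lineage of a marker is independently
replaced by a lineage from an external gene pool with probability ``m``
each generation.  After ``G`` generations the expected surviving
founder-lineage fraction is the geometric survival

    f = (1 - m) ** G        <=>        m = 1 - f ** (1 / G)

Applied per marker, the model converts the present-day founder-origin
(e.g. South Asian) lineage proportion into a per-generation gene-flow rate;
comparing the maternal (mtDNA) and paternal (MSY) rates quantifies
sex-biased admixture.  An additive alternative, ``m = (1 - f) / G`` (total
external fraction spread evenly over generations), is provided for
comparison but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, MetadataError
from .haplogroups import HaplogroupCall
from .sequence_io import SampleTable
from .synthetic_data import expected_founder_fraction

__all__ = [
    "GeneFlowEstimate",
    "rate_from_fraction",
    "fraction_from_rate",
    "additive_rate_from_fraction",
    "estimate_from_calls",
]


def rate_from_fraction(f: float, generations: int) -> float:
    """Per-generation replacement rate implied by a retained founder fraction."""
    if not (0 < f <= 1):
        raise DegenerateInputError(f"retained fraction f={f} must be in (0, 1]")
    if generations < 1:
        raise DegenerateInputError("generations must be >= 1")
    return 1.0 - f ** (1.0 / generations)


def fraction_from_rate(m: float, generations: int) -> float:
    """Forward direction of the model; alias of the simulator's expectation."""
    return expected_founder_fraction(m, generations)


def additive_rate_from_fraction(f: float, generations: int) -> float:
    """Non-default additive-flow alternative: total external fraction spread
    uniformly over the generations."""
    if not (0 < f <= 1):
        raise DegenerateInputError(f"retained fraction f={f} must be in (0, 1]")
    return (1.0 - f) / generations


@dataclass
class GeneFlowEstimate:
    marker: str
    f: float                      # retained founder-origin fraction
    generations: int
    m: float                      # per-generation rate under geometric survival
    ci_low: float
    ci_high: float
    n: int
    founder_origin: str
    n_boot: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "founder_origin": self.founder_origin,
            "f": self.f,
            "generations": self.generations,
            "m": self.m,
            "m_percent": 100.0 * self.m,
            "ci95_low": self.ci_low,
            "ci95_high": self.ci_high,
            "n": self.n,
        }


def estimate_from_calls(calls: Sequence[HaplogroupCall] | Sequence[str] | dict,
                        table: SampleTable | None,
                        founder_origin: str = "South Asian",
                        generations: int = 50,
                        n_boot: int = 1_000,
                        seed: int | None = None) -> dict[str, GeneFlowEstimate]:
    """Per-marker gene-flow rate from origin-labelled haplogroup calls.

    ``calls`` may be :class:`HaplogroupCall` objects (joined to ``table``
    for the marker), or a mapping ``marker -> list of origin labels``.
    The retained fraction ``f`` is the proportion of calls whose origin is
    ``founder_origin``; the CI is a seeded percentile bootstrap over samples
    mapped through the model.
    """
    per_marker: dict[str, list[str]] = {}
    if isinstance(calls, dict):
        per_marker = {k: list(v) for k, v in calls.items()}
    else:
        if table is None:
            raise MetadataError("a SampleTable is required to split calls by marker")
        markers = table.df.set_index("sample_id")["marker"]
        for c in calls:
            if c.sample_id not in markers.index:
                raise MetadataError(f"call for unknown sample {c.sample_id!r}")
            per_marker.setdefault(str(markers[c.sample_id]), []).append(c.origin)

    if not per_marker:
        raise DegenerateInputError("no calls supplied")

    rng = np.random.default_rng(seed)
    out: dict[str, GeneFlowEstimate] = {}
    for marker, origins in per_marker.items():
        is_founder = np.asarray([o == founder_origin for o in origins], dtype=bool)
        n = is_founder.size
        f = float(is_founder.mean())
        if f == 0:
            raise DegenerateInputError(
                f"no {founder_origin!r} lineages in marker {marker!r}: "
                "retained fraction is 0 and the rate is undefined"
            )
        m = rate_from_fraction(f, generations)
        boots = []
        for _ in range(n_boot):
            fb = float(is_founder[rng.integers(0, n, size=n)].mean())
            if fb == 0:
                fb = 0.5 / n  # continuity floor for an empty resample
            boots.append(rate_from_fraction(fb, generations))
        lo, hi = np.percentile(boots, [2.5, 97.5])
        out[marker] = GeneFlowEstimate(
            marker=marker, f=f, generations=generations, m=m,
            ci_low=float(lo), ci_high=float(hi), n=n,
            founder_origin=founder_origin, n_boot=n_boot, seed=seed,
        )
    return out
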