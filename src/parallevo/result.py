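"""Container for hypothesis-test results with full provenance."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict


@dataclass
class TestResult:
    """Outcome of a directional hypothesis test.

    Attributes
    ----------
    method : str
        Label identifying the test ("angle", "schott", "rayleigh",
        "mean_pairwise_angle").
    statistic : float
        The test statistic on its natural scale (an angle in radians,
        a sum of squared correlations, a Rayleigh score, ...).
    p_value : float
        Probability in [0, 1].
    n : int, optional
        Number of lineages (direction vectors) entering the test.
    k : int, optional
        Effective dimensionality of the trait space.
    null_mean, null_sd : float, optional
        Moments of the statistic under the uniform-direction null, when a
        closed form or a Monte Carlo estimate is available.
    alternative : str, optional
        Which departure from the null counts as extreme.
    mc_iterations : int, optional
        Number of Monte Carlo replicates (None for purely analytic tests).
    seed : int, optional
        RNG seed; recorded whenever Monte Carlo is used.
    details : dict
        Method-specific extras (angle in degrees, vector correlation r,
        t statistic, Z score, sampler algorithm ...).
    notes : list of str
        Warnings and caveats, e.g. the non-independence of pairwise angles
        or the small-sample regime of the asymptotic Schott test.
    """

    method: str
    statistic: float
    p_value: float
    n: int | None = None
    k: int | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    alternative: str | None = None
    mc_iterations: int | None = None
    seed: int | None = None
    details: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.null_sd is not None and self.null_sd <= 0:
            raise ValueError("null_sd must be positive when defined")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __str__(self) -> str:  # compact human-readable one-liner
        parts = [f"{self.method}: statistic={self.statistic:.6g}",
                 f"p={self.p_value:.4g}"]
        if self.k is not None:
            parts.append(f"k={self.k}")
        if self.n is not None:
            parts.append(f"n={self.n}")
        return ", ".join(parts)
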