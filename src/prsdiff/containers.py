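"""In-memory containers passed between stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix.

    ``dosages`` is float with values in [0, 2] (hard calls are 0/1/2) and
    ``nan`` marking missing genotypes.  Row order matches ``samples``,
    column order matches ``variant_ids``.
    """

    dosages: np.ndarray
    samples: list[str]
    variant_ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.variant_ids):
            raise ValidationError("dosage shape inconsistent with sample/variant ids")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column_index(self) -> dict[str, int]:
        return {v: j for j, v in enumerate(self.variant_ids)}

    def subset_variants(self, keep_ids) -> "GenotypeMatrix":
        """Return a copy restricted to ``keep_ids`` (order preserved)."""
        idx = self.column_index()
        cols = [idx[v] for v in keep_ids if v in idx]
        kept = [v for v in keep_ids if v in idx]
        return GenotypeMatrix(self.dosages[:, cols].copy(), list(self.samples), kept)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.samples, columns=self.variant_ids)
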