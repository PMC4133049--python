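"""The binary fate panel: ±1 transcription-factor states of the natural cell fates.

The panel (symbol Xi, columns = fates, rows = TFs) is the only biological
input to the landscape.  Everything downstream — the fate correlation
matrix, the projector couplings, predictivity — is a deterministic function
of it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyIntersectionError, ValidationError


@dataclass(frozen=True)
class FatePanel:
    """N x p matrix of ±1 TF states for p named cell fates.

    Parameters
    ----------
    tf_ids : tuple of str
        Ordered transcription-factor identifiers (length N).
    fate_names : tuple of str
        Ordered, unique cell-fate names (length p).
    xi : ndarray of shape (N, p)
        Entries strictly in {-1, +1}.  Requires N > p so the fate patterns
        span a proper subspace of expression space.
    """

    tf_ids: tuple
    fate_names: tuple
    xi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "tf_ids", tuple(self.tf_ids))
        object.__setattr__(self, "fate_names", tuple(self.fate_names))
        xi = np.asarray(self.xi)
        if xi.ndim != 2:
            raise ValidationError("xi must be a 2-D (TF x fate) matrix")
        if not np.isin(xi, (-1, 1)).all():
            raise ValidationError("panel entries must be strictly +1 or -1")
        xi = xi.astype(np.int8)
        xi.setflags(write=False)
        object.__setattr__(self, "xi", xi)
        n, p = xi.shape
        if len(self.tf_ids) != n:
            raise ValidationError(f"{len(self.tf_ids)} tf_ids for {n} rows")
        if len(self.fate_names) != p:
            raise ValidationError(f"{len(self.fate_names)} fate names for {p} columns")
        if p < 1:
            raise ValidationError("need at least one fate")
        if n <= p:
            raise ValidationError(
                f"need more TFs than fates for a proper fate subspace (N={n}, p={p})"
            )
        if len(set(self.fate_names)) != p:
            raise ValidationError("fate names must be unique")
        if len(set(self.tf_ids)) != n:
            raise ValidationError("tf ids must be unique")

    @property
    def n_tfs(self) -> int:
        return self.xi.shape[0]

    @property
    def n_fates(self) -> int:
        return self.xi.shape[1]

    def fate_index(self, name: str) -> int:
        try:
            return self.fate_names.index(name)
        except ValueError:
            raise ValidationError(
                f"unknown fate {name!r}; known fates: {list(self.fate_names)}"
            ) from None

    def pattern(self, name: str) -> np.ndarray:
        """Return the ±1 expression pattern of one fate as a float vector."""
        return self.xi[:, self.fate_index(name)].astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.xi), index=list(self.tf_ids), columns=list(self.fate_names)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FatePanel":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy())

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="tf")

    @classmethod
    def from_tsv(cls, path) -> "FatePanel":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))

    def restrict(self, tf_subset) -> "FatePanel":
        """Restrict to the TFs in ``tf_subset``, keeping this panel's order.

        Any correlation/coupling matrices built from the full panel are
        invalid for the restricted one and must be rebuilt.
        """
        keep = set(tf_subset)
        idx = [i for i, t in enumerate(self.tf_ids) if t in keep]
        if not idx:
            raise EmptyIntersectionError("no TFs left after restriction")
        ids = tuple(self.tf_ids[i] for i in idx)
        return FatePanel(ids, self.fate_names, self.xi[idx, :])
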