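"""Design-matrix container with intercept handling and standardization.

The design matrix is stored as an ``n x (p+1)`` array whose first column is
an intercept column of ones.  Continuous covariates are optionally centered
and scaled to standard deviation 0.5, which puts coefficients of continuous
and binary covariates on roughly comparable scales; the center/scale
metadata is kept so coefficients can be mapped back to the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignMatrix"]

INTERCEPT_NAME = "(Intercept)"


@dataclass
class DesignMatrix:
    """Numeric design matrix with a leading intercept column.

    Parameters
    ----------
    values : ndarray, shape (n, p+1)
        Covariate values including the intercept column of ones (column 0).
    column_names : list of str
        Unique labels, length p+1; ``column_names[0]`` is the intercept.
    center, scale : ndarray, shape (p+1,)
        Standardization metadata: ``values[:, j] = (raw[:, j] - center[j]) / scale[j]``.
        Identity (0, 1) for the intercept and for unstandardized columns.
    """

    values: np.ndarray
    column_names: list[str]
    center: np.ndarray = field(default=None)
    scale: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design matrix must be 2-dimensional")
        n, p1 = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design matrix contains non-finite values")
        if not np.allclose(self.values[:, 0], 1.0):
            raise ValueError("column 0 must be an intercept column of ones")
        if len(self.column_names) != p1:
            raise ValueError("column_names length does not match column count")
        if len(set(self.column_names)) != p1:
            raise ValueError("column names must be unique")
        if self.center is None:
            self.center = np.zeros(p1)
        if self.scale is None:
            self.scale = np.ones(p1)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_array(
        cls,
        X: np.ndarray,
        column_names: list[str] | None = None,
        add_intercept: bool = True,
        standardize: bool = False,
        target_sd: float = 0.5,
    ) -> "DesignMatrix":
        """Build from a raw covariate array (without intercept by default).

        With ``standardize=True`` every non-binary column is centered and
        scaled to standard deviation ``target_sd``; binary columns (at most
        two distinct values) are left alone.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, p = X.shape
        if column_names is None:
            column_names = [f"x{j + 1}" for j in range(p)]
        column_names = list(column_names)
        if add_intercept:
            values = np.column_stack([np.ones(n), X])
            column_names = [INTERCEPT_NAME] + column_names
        else:
            values = X.copy()
        p1 = values.shape[1]
        center = np.zeros(p1)
        scale = np.ones(p1)
        if standardize:
            for j in range(1, p1):
                col = values[:, j]
                if np.unique(col).size <= 2:
                    continue
                sd = col.std(ddof=1)
                if sd <= 0:
                    continue
                center[j] = col.mean()
                scale[j] = sd / target_sd
                values[:, j] = (col - center[j]) / scale[j]
        return cls(values, column_names, center, scale)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DesignMatrix":
        return cls.from_array(df.to_numpy(dtype=float), list(df.columns), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DesignMatrix":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)

    # -- accessors --------------------------------------------------------

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        """Number of non-intercept covariates."""
        return self.values.shape[1] - 1

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def columns(self, indices) -> np.ndarray:
        return self.values[:, np.asarray(indices, dtype=int)]

    def transform(self, X_raw: np.ndarray) -> np.ndarray:
        """Apply this matrix's standardization to new raw covariates."""
        X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
        if X_raw.shape[1] == self.p:
            X_raw = np.column_stack([np.ones(X_raw.shape[0]), X_raw])
        return (X_raw - self.center) / self.scale

    def raw_scale_coef(self, coef: np.ndarray) -> np.ndarray:
        """Map coefficients on the standardized scale back to the raw scale."""
        coef = np.asarray(coef, dtype=float)
        out = coef / self.scale
        out[0] = coef[0] - np.sum(coef[1:] * self.center[1:] / self.scale[1:])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)
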