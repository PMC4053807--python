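"""SNR-to-Kd affinity calibration and in-silico spacer disruption.

In-vitro binding assays give dissociation constants (Kd, nM) for RNA
probes; the same probe sequences have measurable SNR enrichment in CLIP
sites. Kd follows a power curve in the reciprocal of the SNR,

    Kd = a * (1/SNR)^b,

fitted by ordinary least squares in log10-log10 space (multiplicative
error). The fitted curve predicts Kd for arbitrary sequences via their SNR,
which supports in-silico experiments such as disrupting the tandem
half-sites of the octamer with spacers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .models import to_rna
from .motifs import HALFSITE, OCTAMER, compute_snr


@dataclass(frozen=True)
class ProbeRecord:
    """One in-vitro probe: sequence, association/dissociation constants and
    its SNR in sites vs background."""

    sequence: str
    kd: float              # nM
    snr: float
    K: Optional[float] = None  # association constant, 1/Kd units


@dataclass(frozen=True)
class AffinityCalibration:
    """Fitted power-law map between SNR and Kd.

    ``r_log`` is the Pearson correlation between log10(Kd) and log10(1/SNR).
    """

    a: float
    b: float
    r_log: float
    n_points: int

    def predict(self, snr) -> np.ndarray | float:
        return predict_kd(self, snr)


class InsufficientDataError(ValueError):
    pass


class PowerLawCalibrator:
    """Scikit-learn-style estimator for the SNR -> Kd power curve.

    fit(snr, kd) performs OLS of log10(kd) on log10(1/snr); fitted
    attributes are ``a_`` (scale, nM), ``b_`` (exponent), ``r_log_`` and
    ``n_points_``. Probes with nonpositive Kd or SNR are excluded with a
    warning. Duplicated probe rows act as weights (they change the fit).
    """

    def __init__(self):
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "PowerLawCalibrator":
        for k in params:
            raise ValueError(f"unknown parameter {k!r}")
        return self

    def fit(self, snr, kd) -> "PowerLawCalibrator":
        snr = np.asarray(snr, dtype=float).ravel()
        kd = np.asarray(kd, dtype=float).ravel()
        if snr.shape != kd.shape:
            raise ValueError("snr and kd must have the same length")
        usable = (snr > 0) & (kd > 0) & np.isfinite(snr) & np.isfinite(kd)
        n_excluded = int((~usable).sum())
        if n_excluded:
            warnings.warn(f"excluded {n_excluded} probes with nonpositive or "
                          f"non-finite Kd/SNR", stacklevel=2)
        if usable.sum() < 3:
            raise InsufficientDataError(
                f"need >=3 usable probes, got {int(usable.sum())}")
        x = np.log10(1.0 / snr[usable])
        y = np.log10(kd[usable])
        b, log_a = np.polyfit(x, y, 1)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        self.a_ = float(10.0 ** log_a)
        self.b_ = float(b)
        self.r_log_ = r
        self.n_points_ = int(usable.sum())
        self.n_excluded_ = n_excluded
        return self

    def predict(self, snr):
        self._check_fitted()
        return predict_kd(self.calibration_, snr)

    @property
    def calibration_(self) -> AffinityCalibration:
        self._check_fitted()
        return AffinityCalibration(self.a_, self.b_, self.r_log_,
                                   self.n_points_)

    def _check_fitted(self):
        if not hasattr(self, "a_"):
            raise AttributeError("calibrator is not fitted; call fit first")


def fit_power_curve(probes) -> AffinityCalibration:
    """Fit the calibration from a probe table.

    ``probes`` is a DataFrame with columns ``snr`` and ``kd_nM`` (or ``kd``),
    or a sequence of :class:`ProbeRecord`.
    """
    if hasattr(probes, "columns"):
        snr = probes["snr"].to_numpy()
        kd_col = "kd_nM" if "kd_nM" in probes.columns else "kd"
        kd = probes[kd_col].to_numpy()
    else:
        snr = np.array([p.snr for p in probes], float)
        kd = np.array([p.kd for p in probes], float)
    return PowerLawCalibrator().fit(snr, kd).calibration_


def predict_kd(calibration: AffinityCalibration, snr):
    """Kd = a * (1/snr)^b; strictly decreasing in snr for b > 0."""
    arr = np.asarray(snr, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("snr must be positive")
    out = calibration.a * (1.0 / arr) ** calibration.b
    return float(out) if np.isscalar(snr) or arr.ndim == 0 else out


def spacer_variants(max_spacer: int = 4) -> list[dict]:
    """Half-site pairs interrupted by 0..max_spacer identical nucleotides.

    Spacer length 0 is the intact octamer (the two UAUU half-sites abut).
    Spacer bases are U (uridylate) or each non-uridylate V in {A, C, G}.
    """
    rows = [{"spacer_len": 0, "spacer_base": "", "kind": "octamer",
             "sequence": OCTAMER}]
    for L in range(1, max_spacer + 1):
        for base in "UACG":
            rows.append({"spacer_len": L, "spacer_base": base,
                         "kind": "U" if base == "U" else "V",
                         "sequence": HALFSITE + base * L + HALFSITE})
    return rows


def spacer_scan(calibration: AffinityCalibration,
                site_seqs: Sequence[str], background_seqs: Sequence[str],
                max_spacer: int = 4):
    """Predicted Kd for half-sites interrupted by 1-4 uridylates or
    non-uridylates (V = A/C/G, averaged).

    Each variant's SNR is computed from the provided site and background
    sequence sets and mapped through the calibration. Variants absent from
    the background have undefined SNR and NaN Kd. Rows with
    ``spacer_base == 'V'`` are the mean over the three per-base variants.
    """
    import pandas as pd

    rows = []
    for var in spacer_variants(max_spacer):
        res = compute_snr(site_seqs, background_seqs, var["sequence"])
        snr = res.snr
        kd = predict_kd(calibration, snr) if np.isfinite(snr) and snr > 0 \
            else float("nan")
        rows.append({**var, "snr": snr, "kd_nM": kd})
    df = pd.DataFrame(rows)

    v_rows = []
    for L in range(1, max_spacer + 1):
        sub = df[(df.spacer_len == L) & (df.kind == "V")]
        v_rows.append({"spacer_len": L, "spacer_base": "V", "kind": "V_mean",
                       "sequence": f"{HALFSITE}V{{{L}}}{HALFSITE}",
                       "snr": sub["snr"].mean(), "kd_nM": sub["kd_nM"].mean()})
    return pd.concat([df, pd.DataFrame(v_rows)], ignore_index=True)


def probe_snr_table(probes, site_seqs, background_seqs):
    """Recompute each probe's SNR from sequence sets, keeping probes whose
    sequence occurs at least once in the sites (others have no defined
    enrichment and are dropped from fitting)."""
    import pandas as pd

    rows = []
    for rec in probes.itertuples(index=False):
        seq = to_rna(rec.sequence)
        res = compute_snr(site_seqs, background_seqs, seq)
        if res.site_occurrences == 0:
            continue
        rows.append({"sequence": seq, "snr": res.snr,
                     "kd_nM": getattr(rec, "kd_nM", getattr(rec, "kd", None))})
    return pd.DataFrame(rows)
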