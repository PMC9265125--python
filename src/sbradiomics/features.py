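"""Per-case feature assembly, canonical naming and z-score normalization.

Column naming follows "{bins}_{seq}_{subband}_{family}_{name}" where the
bins token is log2(bins) rendered as e.g. "6bit" (64 bins), the bins field
is "-" for intensity features, and histogram features always carry "6bit"
(their quantization is fixed to 64 levels). Morphology features depend on
the mask only and are rendered "{seq}_MORPH_{name}" (no bins or subband
tokens). Per sequence the table has

    8 + 9*(18 + 20) + 9*4*(11 + 13 + 13 + 16 + 5) = 2438

columns; a two-sequence case has 4876.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .discretize import HISTOGRAM_BINS, TEXTURE_BIN_COUNTS, quantize
from .firstorder import histogram_features, intensity_features, morphology_features
from .image_io import VoiMask, VolumeImage
from .registry import TEXTURE_FAMILIES, family_features, load_registry, registry_version
from .texture import TEXTURE_FAMILY_FUNCS
from .wavelet import SUBBAND_LABELS, decompose

#: number of feature columns per image sequence / per two-sequence case
FEATURES_PER_SEQUENCE = 2438
FEATURES_PER_CASE = 2 * FEATURES_PER_SEQUENCE

LABEL_COLUMN = "label"

_BIT_TOKEN = {16: "4bit", 32: "5bit", 64: "6bit", 128: "7bit"}


def bins_token(n_bins: int) -> str:
    return _BIT_TOKEN[n_bins]


def sequence_of(feature_name: str) -> str:
    """Sequence role ("GD"/"T2") encoded in a canonical feature name."""
    parts = feature_name.split("_")
    return parts[0] if parts[1] == "MORPH" else parts[1]


def sequence_feature_names(seq: str) -> list[str]:
    """Canonical column names of one sequence, in registry order."""
    names = [f"{seq}_MORPH_{n}" for n in family_features("MORPH")]
    for sub in SUBBAND_LABELS:
        names += [f"-_{seq}_{sub}_INT_{n}" for n in family_features("INT")]
        names += [
            f"{bins_token(HISTOGRAM_BINS)}_{seq}_{sub}_HIST_{n}"
            for n in family_features("HIST")
        ]
    for sub in SUBBAND_LABELS:
        for nb in TEXTURE_BIN_COUNTS:
            for fam in TEXTURE_FAMILIES:
                names += [
                    f"{bins_token(nb)}_{seq}_{sub}_{fam}_{n}"
                    for n in family_features(fam)
                ]
    return names


def extract_sequence(
    volume: VolumeImage, mask: VoiMask, seq: str
) -> "OrderedDict[str, float]":
    """Extract the full 2438-feature vector for one sequence volume.

    Runs the wavelet decomposition, then per image the intensity features,
    the 64-level histogram features and the texture families at 16/32/64/
    128 levels; morphology is computed once from the mask.
    """
    load_registry()  # refuse to run on a corrupt registry
    out: "OrderedDict[str, float]" = OrderedDict()
    morph = morphology_features(mask)
    for n in family_features("MORPH"):
        out[f"{seq}_MORPH_{n}"] = morph[n]
    subbands = decompose(volume)
    quantized = {}
    for sub in SUBBAND_LABELS:
        img = subbands[sub]
        inten = intensity_features(img, mask)
        for n in family_features("INT"):
            out[f"-_{seq}_{sub}_INT_{n}"] = inten[n]
        q64 = quantize(img, mask, HISTOGRAM_BINS, sub)
        quantized[(sub, HISTOGRAM_BINS)] = q64
        hist = histogram_features(q64)
        for n in family_features("HIST"):
            out[f"{bins_token(HISTOGRAM_BINS)}_{seq}_{sub}_HIST_{n}"] = hist[n]
    for sub in SUBBAND_LABELS:
        for nb in TEXTURE_BIN_COUNTS:
            q = quantized.get((sub, nb))
            if q is None:
                q = quantize(subbands[sub], mask, nb, sub)
            for fam in TEXTURE_FAMILIES:
                vals = TEXTURE_FAMILY_FUNCS[fam](q)
                for n in family_features(fam):
                    out[f"{bins_token(nb)}_{seq}_{sub}_{fam}_{n}"] = vals[n]
    if len(out) != FEATURES_PER_SEQUENCE:
        raise RuntimeError(
            f"extracted {len(out)} features per sequence, expected "
            f"{FEATURES_PER_SEQUENCE}"
        )
    return out


def extract_case(volumes: dict[str, VolumeImage], mask: VoiMask) -> pd.Series:
    """Full per-case feature vector (both sequences), deterministic and in
    registry column order."""
    out: "OrderedDict[str, float]" = OrderedDict()
    for seq in sorted(volumes):
        try:
            out.update(extract_sequence(volumes[seq], mask, seq))
        except Exception as exc:  # attach sequence context
            raise type(exc)(f"[sequence {seq}] {exc}") from exc
    vec = pd.Series(out, dtype=np.float64)
    if not np.all(np.isfinite(vec.to_numpy())):
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()[:5]
        raise ValueError(f"non-finite features extracted: {bad}")
    return vec


def extract_cohort(cases: Iterable) -> pd.DataFrame:
    """Feature table for a cohort of synthetic (or loaded) cases.

    Rows are case ids; the first column is the class label, followed by the
    features in canonical order. Provenance (registry version) is stored in
    ``DataFrame.attrs``.
    """
    rows, labels, ids = [], [], []
    for case in cases:
        try:
            rows.append(extract_case(case.volumes, case.mask))
        except Exception as exc:
            raise type(exc)(f"[case {case.case_id}] {exc}") from exc
        labels.append(case.label)
        ids.append(case.case_id)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="case_id"))
    table.insert(0, LABEL_COLUMN, labels)
    table.attrs["registry_version"] = registry_version()
    return table


def split_xy(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """(features, labels) view of a feature table."""
    return table.drop(columns=[LABEL_COLUMN]), table[LABEL_COLUMN].to_numpy()


def zscore_fit(train: pd.DataFrame) -> pd.DataFrame:
    """Per-column mean and sample (N-1) standard deviation of the training
    table, with constant columns flagged."""
    if len(train) < 2:
        raise ValueError("z-score normalization needs at least 2 training rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    return pd.DataFrame({"mean": mean, "sd": sd, "constant": sd == 0.0})


def zscore_apply(table: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Apply training normalization statistics; constant columns map to 0."""
    sd = stats["sd"].where(~stats["constant"], 1.0)
    out = (table - stats["mean"]) / sd
    if stats["constant"].any():
        out.loc[:, stats.index[stats["constant"]]] = 0.0
    return out


def zscore_fit_apply(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Fit normalization on the training table only and apply it to the
    training table and every other table (never refit on validation data).

    Returns ([normalized_train, normalized_others...], stats).
    """
    stats = zscore_fit(train)
    normalized = [zscore_apply(train, stats)]
    normalized += [zscore_apply(t, stats) for t in others]
    return normalized, stats


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="case_id")
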