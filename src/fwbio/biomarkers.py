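"""Region-of-interest biomarkers: ROI means, signature composites, TIV adjustment.

Turns voxel maps and morphometry tables into the nine per-participant
biomarkers used downstream: hippocampal {TIV-adjusted volume, FW,
FW-corrected FA} and, for each of two AD-signature meta-ROI definitions
(Schwarz-style thickness composite; McEvoy-style thickness + hippocampal
volume composite), the structural composite plus FW and FW-corrected FA
averaged over the signature regions.

Published signature weights are external to this package; the shipped
defaults weight the canonical temporal-lobe regions equally and are a
documented placeholder, with :class:`SignatureDefinition` accepting any
weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .freewater import FWMaps

__all__ = [
    "ROILabelMap",
    "SignatureDefinition",
    "roi_mean",
    "weighted_region_combine",
    "tiv_adjust_volume",
    "hippocampal_volume_total",
    "build_biomarker_table",
    "default_schwarz_signature",
    "default_mcevoy_signature",
]

SIGNATURE_REGIONS = ("entorhinal", "fusiform", "inferior_temporal", "middle_temporal")


@dataclass
class ROILabelMap:
    """Integer label grid plus id -> region-name dictionary (0 = background)."""

    labels: np.ndarray
    names: dict

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer-valued")
        if 0 in self.names:
            raise ValueError("label 0 is reserved for background")

    def ids_for(self, region: str) -> list:
        """Label ids whose name is ``region`` or ``region_{left,right}``."""
        wanted = {region, f"{region}_left", f"{region}_right"}
        return [i for i, nm in self.names.items() if nm in wanted]


@dataclass(frozen=True)
class SignatureDefinition:
    """A weighted meta-ROI composite.

    terms : list of (region name, weight, measure) with measure in
        {"thickness", "volume"}
    normalization : "weighted_mean" (sum w*x / sum w) or "sum"
    zscore_terms : z-score each term across participants before weighting
        (needed to mix thickness with volume on one scale)
    """

    name: str
    terms: tuple
    normalization: str = "weighted_mean"
    zscore_terms: bool = False

    def __post_init__(self) -> None:
        if len(self.terms) < 1:
            raise ValueError("signature needs at least one term")
        for region, w, measure in self.terms:
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight for region {region!r}")
            if measure not in ("thickness", "volume"):
                raise ValueError(f"unknown measure {measure!r}")
        if self.normalization not in ("weighted_mean", "sum"):
            raise ValueError("normalization must be 'weighted_mean' or 'sum'")

    @property
    def thickness_regions(self) -> list:
        return [r for r, _, m in self.terms if m == "thickness"]


def default_schwarz_signature() -> SignatureDefinition:
    terms = tuple((r, 1.0, "thickness") for r in SIGNATURE_REGIONS)
    return SignatureDefinition("schwarz", terms)


def default_mcevoy_signature() -> SignatureDefinition:
    terms = tuple((r, 1.0, "thickness") for r in SIGNATURE_REGIONS)
    terms = terms + (("hippocampus", 1.0, "volume"),)
    return SignatureDefinition("mcevoy", terms, zscore_terms=True)


def roi_mean(value_map, labels: ROILabelMap, region_ids, exclude_flags=None) -> float:
    """Unweighted mean of a scalar map over the voxels of the given labels.

    ``exclude_flags`` (boolean map, True = drop) removes voxels, e.g. those
    flagged degenerate by the free-water fit.  An empty region is an error.
    """
    value_map = np.asarray(value_map, dtype=float)
    if value_map.shape != labels.labels.shape:
        raise ValueError("map and label grid shapes differ")
    region_ids = list(np.atleast_1d(region_ids))
    sel = np.isin(labels.labels, region_ids)
    if exclude_flags is not None:
        sel &= ~np.asarray(exclude_flags, dtype=bool)
    if not np.any(sel):
        names = [labels.names.get(i, f"label {i}") for i in region_ids]
        raise ValueError(f"region {names} is empty after exclusions")
    return float(value_map[sel].mean())


def weighted_region_combine(region_values: dict, signature: SignatureDefinition) -> float:
    """Combine per-region scalars with the signature's weights."""
    w = []
    x = []
    for region, weight, _measure in signature.terms:
        if region not in region_values:
            raise KeyError(f"region {region!r} missing from region_values")
        w.append(weight)
        x.append(region_values[region])
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    if signature.normalization == "weighted_mean":
        if np.sum(np.abs(w)) == 0:
            raise ValueError("all-zero weights")
        return float(np.sum(w * x) / np.sum(w))
    return float(np.sum(w * x))


def tiv_adjust_volume(volumes: pd.Series, tiv: pd.Series, reference_ids) -> pd.Series:
    """Residual-method head-size adjustment of a regional volume.

    A line ``volume = a + b * TIV`` is fit by least squares within the
    reference participants (conventionally the cognitively unimpaired);
    every participant's adjusted value is the residual from that line.
    Reference-subset residuals average to zero by construction.
    """
    volumes = pd.Series(volumes, dtype=float)
    tiv = pd.Series(tiv, dtype=float)
    ref = pd.Index(reference_ids)
    if len(ref) < 3:
        raise ValueError("need at least 3 reference participants")
    t_ref = tiv.loc[ref]
    v_ref = volumes.loc[ref]
    if np.isclose(t_ref.var(ddof=0), 0.0):
        raise ValueError("TIV is constant in the reference set")
    b, a = np.polyfit(t_ref.to_numpy(), v_ref.to_numpy(), 1)
    return volumes - (a + b * tiv)


def hippocampal_volume_total(morph: pd.DataFrame) -> pd.Series:
    """Left + right hippocampal volume (mm^3), indexed by participant."""
    for col in ("hippocampus_left_volume", "hippocampus_right_volume"):
        if col not in morph.columns:
            raise KeyError(f"morphometry table lacks {col!r}")
    if (morph["hippocampus_left_volume"] <= 0).any() or (
            morph["hippocampus_right_volume"] <= 0).any():
        warnings.warn("zero or negative hippocampal volume on one side",
                      stacklevel=2)
    total = morph["hippocampus_left_volume"] + morph["hippocampus_right_volume"]
    total.index = morph["participant_id"]
    return total


def _bilateral_mean(value_map, labels: ROILabelMap, region: str, exclude=None) -> float:
    """Average the left/right ROI means (sides weighted equally)."""
    ids = labels.ids_for(region)
    if not ids:
        raise KeyError(f"no labels found for region {region!r}")
    return float(np.mean([roi_mean(value_map, labels, i, exclude) for i in ids]))


def _thickness_value(morph_row: pd.Series, region: str) -> float:
    cols = [c for c in (f"thickness_{region}_left", f"thickness_{region}_right",
                        f"thickness_{region}") if c in morph_row.index]
    if not cols:
        raise KeyError(f"thickness for region {region!r} missing")
    return float(np.mean([morph_row[c] for c in cols]))


def build_biomarker_table(
    fwmaps,
    labels: ROILabelMap,
    morph: pd.DataFrame,
    signatures: dict | None = None,
    reference_ids=None,
    exclude_degenerate: bool = False,
) -> pd.DataFrame:
    """Assemble the nine biomarkers for every participant.

    Parameters
    ----------
    fwmaps : a single :class:`FWMaps` (applied to all participants, e.g. a
        phantom study) or a mapping participant_id -> FWMaps
    labels : ROI label map aligned to the diffusion grid
    morph : morphometry table (one row per participant) with
        ``thickness_<region>_<side>``, hippocampal volumes and ``tiv``
    signatures : {"schwarz": SignatureDefinition, "mcevoy": ...}; defaults
        to the equal-weight placeholders
    reference_ids : participants used to fit the TIV-adjustment line
        (default: all)
    exclude_degenerate : drop degenerate-flagged voxels from ROI means
    """
    if signatures is None:
        signatures = {"schwarz": default_schwarz_signature(),
                      "mcevoy": default_mcevoy_signature()}
    ids = list(morph["participant_id"])
    if reference_ids is None:
        reference_ids = ids

    hip_total = hippocampal_volume_total(morph)
    hip_adj = tiv_adjust_volume(hip_total, morph.set_index("participant_id")["tiv"],
                                reference_ids)

    rows = []
    morph_idx = morph.set_index("participant_id")
    for pid in ids:
        maps = fwmaps[pid] if isinstance(fwmaps, dict) else fwmaps
        exclude = maps.flags["degenerate_isotropic"] if exclude_degenerate else None
        try:
            row = {"participant_id": pid,
                   "hippocampal_volume_adj": float(hip_adj.loc[pid])}
            hip_ids = labels.ids_for("hippocampus")
            if not hip_ids:
                raise KeyError("no hippocampus labels in label map")
            row["hippocampal_fw"] = roi_mean(maps.fw, labels, hip_ids, exclude)
            row["hippocampal_fa_fwcorr"] = roi_mean(maps.fa_fwcorr, labels, hip_ids, exclude)
            for key in ("schwarz", "mcevoy"):
                sig = signatures[key]
                fw_vals = {}
                fa_vals = {}
                for region in sig.thickness_regions:
                    fw_vals[region] = _bilateral_mean(maps.fw, labels, region, exclude)
                    fa_vals[region] = _bilateral_mean(maps.fa_fwcorr, labels, region, exclude)
                diff_sig = SignatureDefinition(
                    sig.name, tuple(t for t in sig.terms if t[2] == "thickness"),
                    sig.normalization)
                row[f"{key}_fw"] = weighted_region_combine(fw_vals, diff_sig)
                row[f"{key}_fa_fwcorr"] = weighted_region_combine(fa_vals, diff_sig)
            rows.append(row)
        except (KeyError, ValueError) as err:
            raise type(err)(f"participant {pid}: {err}") from err

    table = pd.DataFrame(rows)

    # structural composites need the full population (z-scoring for mixed
    # thickness/volume signatures)
    for key in ("schwarz", "mcevoy"):
        sig = signatures[key]
        term_values = {}
        for region, _w, measure in sig.terms:
            if measure == "thickness":
                vals = []
                for pid in ids:
                    try:
                        vals.append(_thickness_value(morph_idx.loc[pid], region))
                    except KeyError as err:
                        raise KeyError(f"participant {pid}: {err}") from err
                vals = np.array(vals)
            else:
                vals = hip_adj.loc[ids].to_numpy()
            term_values[region] = vals
        if sig.zscore_terms:
            for region, vals in term_values.items():
                sd = vals.std(ddof=0)
                term_values[region] = (vals - vals.mean()) / sd if sd > 0 else vals - vals.mean()
        combined = [
            weighted_region_combine({r: v[i] for r, v in term_values.items()}, sig)
            for i in range(len(ids))
        ]
        table[f"{key}_signature"] = combined

    ordered = ["participant_id", "hippocampal_volume_adj", "hippocampal_fw",
               "hippocampal_fa_fwcorr", "schwarz_signature", "schwarz_fw",
               "schwarz_fa_fwcorr", "mcevoy_signature", "mcevoy_fw",
               "mcevoy_fa_fwcorr"]
    return table[ordered]
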