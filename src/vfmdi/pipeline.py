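"""End-to-end feature assembly for cohorts of shock records.

Chains the stages: two-stage filtering, delay embedding, quasi-period
density, wavelet/time-domain descriptors, optional PetCO2 summaries — and
exposes a per-training-fold builder for the prototype-distance features so
that prototype selection (per-class medoids) only ever sees training
shocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .phase_space import EmbeddingParams
from .preprocessing import FilterConfig, detrend
from .qpd_pd import (
    QpdParams,
    QuasiPeriodDensity,
    density_for_segment,
    prototype_features,
    select_prototypes,
)
from .types import Outcome, ShockRecord, SignalSegment
from .wavelet_features import dtcwt_decompose, subband_features, time_features

__all__ = ["PipelineConfig", "CohortFeatures", "petco2_features"]


@dataclass
class PipelineConfig:
    """All tunables of the feature-extraction chain, one section per stage."""

    preprocessing: FilterConfig = field(default_factory=FilterConfig)
    phase_space: EmbeddingParams = field(default_factory=EmbeddingParams)
    qpd_pd: QpdParams = field(default_factory=QpdParams)
    n_prototypes: int = 4
    ref_stride: int = 5
    wavelet_levels: int = 5
    amsa_band: Tuple[float, float] = (4.0, 48.0)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load from a YAML file with sections preprocessing / phase_space /
        qpd_pd / wavelet / amsa (all optional)."""
        import yaml

        cfg = yaml.safe_load(open(path)) or {}
        kw = {}
        if "preprocessing" in cfg:
            kw["preprocessing"] = FilterConfig(**cfg["preprocessing"])
        if "phase_space" in cfg:
            ps = dict(cfg["phase_space"])
            kw["ref_stride"] = ps.pop("ref_stride", 5)
            qpd_keys = {k: ps.pop(k) for k in ("eps_fraction", "theiler") if k in ps}
            kw["phase_space"] = EmbeddingParams(**ps)
            cfg.setdefault("qpd_pd", {}).update(qpd_keys)
        if "qpd_pd" in cfg:
            kw["qpd_pd"] = QpdParams(**cfg["qpd_pd"])
        if "wavelet" in cfg:
            kw["wavelet_levels"] = cfg["wavelet"].get("levels", 5)
        if "amsa" in cfg:
            band = cfg["amsa"].get("band", [4.0, 48.0])
            kw["amsa_band"] = (float(band[0]), float(band[1]))
        if "n_prototypes" in cfg:
            kw["n_prototypes"] = int(cfg["n_prototypes"])
        return cls(**kw)


def petco2_features(seg: SignalSegment) -> Dict[str, float]:
    """PetCO2 window summaries: mean level, linear-trend slope, final value."""
    t = seg.times - seg.times[0]
    slope = float(np.polyfit(t, seg.samples, 1)[0])
    return {
        "petco2_mean": float(np.mean(seg.samples)),
        "petco2_slope": slope,
        "petco2_final": float(seg.samples[-1]),
    }


@dataclass
class CohortFeatures:
    """Precomputed per-shock features plus densities for fold-wise KD."""

    static_matrix: pd.DataFrame          # static features + outcome column
    densities: List[QuasiPeriodDensity]
    outcomes: np.ndarray
    groups: np.ndarray                   # patient ids
    shock_ids: List[str]
    config: PipelineConfig

    @classmethod
    def from_records(
        cls,
        records: Sequence[ShockRecord],
        config: Optional[PipelineConfig] = None,
        use_petco2: bool = False,
    ) -> "CohortFeatures":
        config = config or PipelineConfig()
        if use_petco2:
            records = [r for r in records if r.petco2 is not None]
        rows, densities, shock_ids = [], [], []
        for rec in records:
            clean = detrend(rec.ecg, config.preprocessing)
            feats: Dict[str, float] = {}
            feats.update(subband_features(dtcwt_decompose(clean, config.wavelet_levels)))
            feats.update(time_features(clean))
            if use_petco2:
                feats.update(petco2_features(rec.petco2))
            dens = density_for_segment(
                clean, config.qpd_pd, config.phase_space, config.ref_stride
            )
            dens.segment_id = rec.shock_id
            densities.append(dens)
            feats["outcome"] = int(rec.outcome)
            rows.append(feats)
            shock_ids.append(rec.shock_id)
        matrix = pd.DataFrame(rows)
        matrix.attrs["metadata"] = {
            "features": [c for c in matrix.columns if c != "outcome"],
            "wavelet_levels": config.wavelet_levels,
            "use_petco2": use_petco2,
        }
        return cls(
            static_matrix=matrix,
            densities=densities,
            outcomes=matrix["outcome"].to_numpy(dtype=int),
            groups=np.array([r.patient_id for r in records]),
            shock_ids=shock_ids,
            config=config,
        )

    def kd_features_for_train(self, train_idx: np.ndarray) -> pd.DataFrame:
        """Prototype-distance features with train-fold-only prototypes.

        Medoid prototypes are chosen among the training shocks; KD features
        are then computed for every shock against those prototypes (no
        label information about test shocks is used).
        """
        dens_train = {self.shock_ids[i]: self.densities[i] for i in train_idx}
        out_train = {
            self.shock_ids[i]: Outcome(int(self.outcomes[i])) for i in train_idx
        }
        ps = select_prototypes(
            dens_train, out_train, self.config.qpd_pd, self.config.n_prototypes
        )
        rows = [prototype_features(d, ps) for d in self.densities]
        return pd.DataFrame(rows)
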