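import numpy as np
import pandas as pd
import pytest

from regennorm import SpikeConfig, SpikeStandard, Tier, regen_v_default


@pytest.fixture
def spike_config() -> SpikeConfig:
    """Default Regen V + BSA configuration (36 µM pre / 54 µM post tiers)."""
    return regen_v_default()


@pytest.fixture
def simple_config() -> SpikeConfig:
    """A minimal one-standard-per-tier configuration with round amounts."""
    return SpikeConfig.validate(
        [
            SpikeStandard("pre1", Tier.PRE_EXTRACTION, 2.0),
            SpikeStandard("post1", Tier.POST_EXTRACTION, 4.0),
            SpikeStandard("BSA", Tier.CARRIER_DIGEST, 6.65),
        ]
    )


def abundance_table(rows) -> pd.DataFrame:
    """Long abundance table from (feature_id, kind, sample_id, value) tuples;
    value None means missing."""
    return pd.DataFrame(
        [
            {
                "feature_id": f,
                "feature_kind": k,
                "sample_id": s,
                "raw_abundance": np.nan if v is None else float(v),
            }
            for f, k, s, v in rows
        ]
    )


def design_table(samples) -> pd.DataFrame:
    """Design frame from (sample_id, batch_id, condition, replicate) tuples."""
    return pd.DataFrame(
        [
            {
                "sample_id": s,
                "batch_id": b,
                "tag_id": f"tag{i}",
                "condition": c,
                "timepoint_days": None,
                "replicate": r,
                "total_protein_ug": 70.0,
                "condition_key": c,
            }
            for i, (s, b, c, r) in enumerate(samples)
        ]
    )
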