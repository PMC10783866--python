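import numpy as np
import pandas as pd


def make_records(times, events, index=None, **covariates) -> pd.DataFrame:
    """Minimal survival-record frame for the statistics tests."""
    idx = index if index is not None else [f"S{i}" for i in range(len(times))]
    df = pd.DataFrame(
        {"os_months": np.asarray(times, float), "os_event": np.asarray(events, int)},
        index=pd.Index(idx, name="sample_id"),
    )
    for name, vals in covariates.items():
        df[name] = vals
    return df
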