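import numpy as np
import pandas as pd
import pytest

from quadhaz import ContinuousParams, LongitudinalRecords


@pytest.fixture(scope="session")
def table4_truth() -> ContinuousParams:
    """1D generating truth of the main parameter-recovery design."""
    return ContinuousParams(a=[[-0.05]], f1=[80.0], b=[5.0], mu0=1e-5,
                            f=[80.0], Q=[[1e-6]], theta=0.1)


@pytest.fixture(scope="session")
def twod_truth() -> ContinuousParams:
    """2D generating truth of the two-covariate recovery design."""
    return ContinuousParams(a=[[-0.05, 0.001], [0.001, -0.05]],
                            f1=[100.0, 200.0], b=[2.0, 5.0], mu0=1e-4,
                            f=[100.0, 200.0],
                            Q=[[1e-6, 1e-7], [1e-7, 1e-6]], theta=0.08)


def make_records(subjects, covariate_names=("DBP",)):
    """Build LongitudinalRecords from per-subject visit specs.

    ``subjects``: dict id -> (times, tau, event, values) where ``values`` is
    (n_visits, k) (or a 1-d list for k=1).
    """
    names = list(covariate_names)
    rows = []
    for sid, (times, tau, event, values) in subjects.items():
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[0] == 1 and len(times) > 1:
            values = values.T
        for j, t in enumerate(times):
            t2 = times[j + 1] if j + 1 < len(times) else tau
            ev = event if j == len(times) - 1 else 0
            rows.append({"id": sid, "event": ev, "t1": t, "t2": t2,
                         **{c: values[j, i] for i, c in enumerate(names)}})
    return LongitudinalRecords(frame=pd.DataFrame(rows), covariate_names=names)
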