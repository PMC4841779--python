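"""Published SH2-domain kinetic-constant panel.

A reference table of first-order recovery time constants for a panel of SH2
(and PTB) domains in EGF-stimulated A431 cells: tau of in vivo membrane
recruitment (live-cell TIRF / single-molecule imaging), the membrane
diffusion constant D of the bound domain, and tau of binding-site creation
measured by far-Western (FW) blotting of matched lysates.  Rows whose FW
timecourse fit the recovery model poorly (R^2 < 0.5) carry ``fw_poor_fit``;
domains with no net recruitment are marked by ``invivo_behavior``.

The headline comparison: in vivo recruitment time constants are on average
several-fold larger than the FW binding-site creation time constants —
membrane recruitment lags the creation of its own binding sites.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

_PANEL_FILE = "sh2_domain_tau_panel.csv"


def load_tau_panel() -> pd.DataFrame:
    """The domain panel as a DataFrame (one row per SH2/PTB probe)."""
    with resources.files("sh2kinetics.data").joinpath(_PANEL_FILE).open() as fh:
        return pd.read_csv(fh)


def recruitment_to_fw_tau_ratios(panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-domain ratio (in vivo recruitment tau) / (FW tau).

    Only rows with both taus numeric and without the FW poor-fit flag
    qualify.  Negative FW taus (decaying band timecourses) are numeric and
    unflagged, so they stay in, giving negative ratios.
    """
    panel = load_tau_panel() if panel is None else panel
    ok = (
        panel["tau_invivo_min"].notna()
        & panel["tau_fw_min"].notna()
        & ~panel["fw_poor_fit"].astype(bool)
    )
    sub = panel[ok].copy()
    sub["tau_ratio"] = sub["tau_invivo_min"] / sub["tau_fw_min"]
    return sub[["domain", "tau_invivo_min", "tau_fw_min", "tau_ratio"]]


def mean_recruitment_to_fw_tau_ratio(panel: pd.DataFrame | None = None) -> float:
    """Mean over qualifying domains of tau_invivo / tau_fw (~6-fold lag)."""
    return float(recruitment_to_fw_tau_ratios(panel)["tau_ratio"].mean())
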