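"""Model / Results interface over the two-step estimation pipeline.

``MultiDiffusionTimeModel`` holds a validated signal table and fit
configuration; ``fit()`` runs the full pipeline and returns a
``MultiDiffusionTimeResults`` carrying per-(subject, session, region)
estimates, diagnostics, a ``summary()`` table, and the downstream
repeatability / validation statistics.

Example
-------
>>> from ivimva import CohortSpec, MultiDiffusionTimeModel, simulate_cohort
>>> table, truth = simulate_cohort(CohortSpec(snr=None, n_subjects=1,
...                                           n_rescans=0), model="va")
>>> res = MultiDiffusionTimeModel(table).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import (
    VELOCITY_METHODS,
    FitConfig,
    FitResult,
    SignalTable,
    results_to_frame,
    run_pipeline,
)
from .stats import RepeatabilityResult, ValidationResult, cov_repeatability, \
    mad_filter, region_summary, validate_lengths

__all__ = ["MultiDiffusionTimeModel", "MultiDiffusionTimeResults"]


class MultiDiffusionTimeModel:
    """Two-compartment IVIM / velocity-autocorrelation model of a signal table.

    Parameters
    ----------
    table : SignalTable or pandas.DataFrame
        ROI-averaged signals in internal units (b: s/mm^2, times: s).
    config : FitConfig, optional
        Pipeline settings; defaults reproduce the study analysis
        (D and f from b = 500/1000, intravascular fits at b < 500 with
        Db = 1.75e-3 mm^2/s, diffusive regime at Delta = 50 ms,
        ballistic at Delta = 11.6 ms).
    """

    def __init__(self, table: SignalTable | pd.DataFrame,
                 config: FitConfig | None = None):
        if isinstance(table, pd.DataFrame):
            table = SignalTable(table)
        self.table = table
        self.config = config or FitConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: FitConfig | None = None
                       ) -> "MultiDiffusionTimeModel":
        return cls(SignalTable(df), config=config)

    @classmethod
    def from_csv(cls, path, config: FitConfig | None = None
                 ) -> "MultiDiffusionTimeModel":
        from .io import read_signal_table
        return cls(read_signal_table(path), config=config)

    def fit(self) -> "MultiDiffusionTimeResults":
        """Run the two-step pipeline for every (subject, session, region)."""
        results = run_pipeline(self.table, self.config)
        return MultiDiffusionTimeResults(model=self, results=results)


@dataclass
class MultiDiffusionTimeResults:
    """Estimates, diagnostics and derived statistics of a fitted model."""

    model: MultiDiffusionTimeModel
    results: list[FitResult]

    @property
    def frame(self) -> pd.DataFrame:
        """Tidy per-(subject, session, region) estimate table."""
        df = results_to_frame(self.results)
        if df.empty:
            return df
        strain_col = self.model.table.data.get("strain")
        if strain_col is not None:
            lut = self.model.table.data.drop_duplicates("subject").set_index(
                "subject")["strain"]
            df.insert(1, "strain", df["subject"].map(lut))
        return df

    def summary(self) -> str:
        """Plain-text per-region summary (MAD-filtered mean +/- SEM)."""
        df = self.frame
        lines = ["Multi-diffusion-time IVIM / velocity-autocorrelation fit",
                 "=" * 72]
        if df.empty:
            lines.append("(no regions fitted)")
            return "\n".join(lines)
        n_subj = df["subject"].nunique()
        lines.append(f"subjects: {n_subj}   sessions: {df['session'].nunique()}"
                     f"   regions: {df['region'].nunique()}")
        lines.append("")
        header = (f"{'region':<22}{'n':>3} {'Dstar':>10} {'v_va':>7} "
                  f"{'v_vab':>7} {'v_sinc':>7} {'l_va_um':>8} {'l_vab_um':>9}")
        lines.append(header)
        lines.append("-" * len(header))
        for region, grp in df.groupby("region", sort=True):
            def m(col, scale=1.0):
                vals = grp[col].to_numpy(dtype=float) * scale
                if not np.isfinite(vals).any():
                    return float("nan"), 0
                s = region_summary(vals)
                return s.mean, s.n
            dstar, n = m("Dstar")
            vva, _ = m("v_va")
            vvab, _ = m("v_vab")
            vsinc, _ = m("v_ivim_ballistic")
            lva, _ = m("l_va", 1e3)
            lvab, _ = m("l_vab", 1e3)
            lines.append(f"{str(region):<22}{n:>3} {dstar:>10.2e} {vva:>7.2f} "
                         f"{vvab:>7.2f} {vsinc:>7.2f} {lva:>8.1f} {lvab:>9.1f}")
        lines.append("")
        lines.append("v in mm/s, Dstar in mm^2/s, l = 6 Dstar / v in micrometres")
        return "\n".join(lines)

    # ---------------- repeatability ----------------

    def repeatability(self, parameters: tuple[str, ...] = (
            "Dstar", "v_va", "v_vab", "l_va", "l_vab")) -> pd.DataFrame:
        """Scan-rescan CoV per (region, parameter) from session pairs.

        Subjects with both session 1 and session 2 contribute one pair.
        """
        df = self.frame
        if df.empty:
            return pd.DataFrame(columns=["region", "parameter", "cov_percent",
                                         "sigma", "mu", "n"])
        s1 = df[df["session"] == 1].set_index(["subject", "region"])
        s2 = df[df["session"] == 2].set_index(["subject", "region"])
        rows = []
        for region in sorted(df["region"].unique()):
            for par in parameters:
                if par not in df.columns:
                    continue
                pairs = []
                for subj in df["subject"].unique():
                    try:
                        a = s1.loc[(subj, region), par]
                        b = s2.loc[(subj, region), par]
                    except KeyError:
                        continue
                    pairs.append((float(a), float(b)))
                if not pairs:
                    continue
                x1, x2 = np.array(pairs).T
                try:
                    r = cov_repeatability(x1, x2)
                except ValueError:
                    continue
                rows.append({"region": region, "parameter": par,
                             "cov_percent": r.cov_percent, "sigma": r.sigma,
                             "mu": r.mu, "n": r.n,
                             "flags": ";".join(r.flags)})
        return pd.DataFrame(rows)

    # ---------------- validation ----------------

    def validate(self, reference_lengths_um: dict, method: str = "vab",
                 sse_about: str = "regression") -> ValidationResult:
        """Compare region-average MR segment lengths (um) with reference lengths.

        ``reference_lengths_um`` maps region label to the reference
        (e.g. micro-CT median) segment length in micrometres; only
        regions present in both are used.
        """
        if method not in VELOCITY_METHODS:
            raise ValueError(f"method must be one of {VELOCITY_METHODS}")
        df = self.frame
        col = f"l_{method}"
        l_mr, l_ref = [], []
        for region, ref in reference_lengths_um.items():
            grp = df.loc[df["region"] == region, col].to_numpy(dtype=float)
            grp = grp[np.isfinite(grp)]
            if len(grp) == 0:
                continue
            kept, _ = mad_filter(grp)
            l_mr.append(float(np.mean(kept)) * 1e3)  # mm -> um
            l_ref.append(float(ref))
        return validate_lengths(l_mr, l_ref, sse_about=sse_about)

    # ---------------- plotting ----------------

    def plot_fit(self, subject, region, session=1, ax=None):
        """Isolated intravascular data with fitted model curves for one region."""
        import matplotlib.pyplot as plt

        from .fitting import average_directions, isolate_intravascular
        from .signal_models import va_H, vab_H

        res = next(r for r in self.results
                   if r.subject == subject and r.session == session
                   and r.region == region)
        cfg = self.model.config
        data = average_directions(self.model.table).data
        grp = data[(data["subject"] == subject) & (data["session"] == session)
                   & (data["region"] == region)]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        bgrid = np.linspace(0, cfg.b_intra_max * 0.99, 200)
        for Delta in sorted(grp["Delta"].unique()):
            D = res.D.get(float(Delta), float("nan"))
            f = res.f.get(float(Delta), float("nan"))
            if not np.isfinite(D) or not np.isfinite(f) or f <= cfg.f_min:
                continue
            g = grp[grp["Delta"] == Delta]
            iso = isolate_intravascular(g, f=f, D=D, Db=cfg.Db,
                                        b_max=cfg.b_intra_max)
            pts = ax.plot(iso["b"], iso["y"], "o",
                          label=f"$\\Delta$ = {Delta * 1e3:.1f} ms")
            if "va" in res.v and np.isfinite(res.T0):
                delta_small = float(g["delta"].iloc[0])
                curve = (np.exp(-bgrid * cfg.Db)
                         * va_H(bgrid, float(Delta), delta_small,
                                res.v["va"], res.T0) + res.d.get("va", 0.0))
                ax.plot(bgrid, curve, "-", color=pts[0].get_color(), alpha=0.7)
        ax.set_xlabel("b (s/mm$^2$)")
        ax.set_ylabel("isolated intravascular signal y")
        ax.set_title(f"{subject} / {region} (VA fit)")
        ax.legend(fontsize=8)
        return ax
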