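"""Model and results objects tying the estimation pipeline together.

:class:`MgremlModel` holds aligned data and the factor-model specification;
``fit()`` runs the canonical transform (once, cached), maximizes the REML
log-likelihood and returns an :class:`MgremlResults` carrying estimates,
standard errors, GLS fixed effects, diagnostics and a ``summary()`` table.
Nested models are compared with ``results.compare(nested_results)``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .data import (
    CovariateData,
    GrmData,
    PhenotypeMatrix,
    align_samples,
    load_covariates,
    load_phenotypes,
    read_grm_binary,
)
from .exceptions import InputError, ModelSpecificationError
from .factors import (
    FactorModelSpec,
    check_identification,
    fix_loading_signs,
    implied_variance_matrices,
    lrt_degrees_of_freedom,
    parse_spec,
    saturated_spec,
)
from .inference import (
    FixedEffectsReport,
    HeritabilityReport,
    LrtResult,
    delta_method_ses,
    gls_fixed_effects,
    heritability_and_correlations,
    likelihood_ratio_test,
    theta_covariance,
)
from .kernel import average_information
from .optim import FitConfig, FitResult, fit_model
from .transform import DEFAULT_LEADING_PCS, canonical_transform, eigendecompose_grm

__all__ = ["MgremlModel", "MgremlResults"]


class MgremlModel:
    """Multivariate GREML model for SNP heritability and genetic correlation.

    Parameters
    ----------
    grm, phenotypes, covariates
        Input data; samples are intersected and complete-cased on
        construction, with the GRM order preserved.
    genetic_model, environmental_model
        Factor-model specifications; both default to saturated (full
        lower-triangular loadings), which can represent any PSD covariance.
    drop_leading_pcs
        Number L of leading GRM principal components eliminated from the
        likelihood (population-stratification control); default 20.
    include_intercept
        Inject a constant covariate applying to every trait (default True).
    """

    def __init__(
        self,
        grm: GrmData,
        phenotypes: PhenotypeMatrix,
        covariates: CovariateData | None = None,
        genetic_model: FactorModelSpec | None = None,
        environmental_model: FactorModelSpec | None = None,
        drop_leading_pcs: int = DEFAULT_LEADING_PCS,
        include_intercept: bool = True,
    ) -> None:
        self.grm, self.phenotypes, self.covariates = align_samples(
            grm, phenotypes, covariates
        )
        traits = self.phenotypes.trait_labels
        self.spec_g = genetic_model or saturated_spec(traits, tag="G")
        self.spec_e = environmental_model or saturated_spec(traits, tag="E")
        for name, spec in (("genetic", self.spec_g), ("environmental", self.spec_e)):
            if spec.trait_labels != traits:
                raise InputError(f"{name} model traits do not match the phenotypes")
        self.drop_leading_pcs = drop_leading_pcs
        self.include_intercept = include_intercept
        self._eigen = None
        self._transformed = None

    @classmethod
    def from_files(
        cls,
        grm_prefix: str | Path,
        pheno_path: str | Path,
        covar_path: str | Path | None = None,
        covar_model_path: str | Path | None = None,
        genetic_model_path: str | Path | None = None,
        environmental_model_path: str | Path | None = None,
        drop_leading_pcs: int = DEFAULT_LEADING_PCS,
        include_intercept: bool = True,
    ) -> "MgremlModel":
        phen = load_phenotypes(pheno_path)
        covar = (
            load_covariates(covar_path, phen.trait_labels, covar_model_path)
            if covar_path is not None
            else None
        )
        spec_g = (
            parse_spec(genetic_model_path, phen.trait_labels)
            if genetic_model_path is not None
            else None
        )
        spec_e = (
            parse_spec(environmental_model_path, phen.trait_labels)
            if environmental_model_path is not None
            else None
        )
        return cls(
            grm=read_grm_binary(grm_prefix),
            phenotypes=phen,
            covariates=covar,
            genetic_model=spec_g,
            environmental_model=spec_e,
            drop_leading_pcs=drop_leading_pcs,
            include_intercept=include_intercept,
        )

    # -- lazily shared expensive pieces ------------------------------------
    @property
    def eigen(self):
        if self._eigen is None:
            self._eigen = eigendecompose_grm(self.grm)
        return self._eigen

    @property
    def transformed(self):
        if self._transformed is None:
            self._transformed = canonical_transform(
                self.eigen,
                self.phenotypes,
                self.covariates,
                L=self.drop_leading_pcs,
                include_intercept=self.include_intercept,
            )
        return self._transformed

    def with_models(
        self,
        genetic_model: FactorModelSpec | None = None,
        environmental_model: FactorModelSpec | None = None,
    ) -> "MgremlModel":
        """Same data and transform, different factor models (EVD is shared)."""
        other = object.__new__(MgremlModel)
        other.__dict__.update(self.__dict__)
        traits = self.phenotypes.trait_labels
        other.spec_g = genetic_model or saturated_spec(traits, tag="G")
        other.spec_e = environmental_model or saturated_spec(traits, tag="E")
        return other

    def fit(
        self,
        config: FitConfig | None = None,
        se: bool = True,
        identification_check: bool = True,
    ) -> "MgremlResults":
        """Maximize the REML log-likelihood; optionally compute AI-based SEs.

        ``se=False`` mirrors the --no-se option: the average-information
        matrix (the expensive post-convergence step) is skipped entirely.
        """
        if identification_check:
            report = check_identification(self.spec_g, self.spec_e)
            if report.over_parameterized or report.jacobian_rank < report.n_free:
                raise ModelSpecificationError(
                    "factor model is not identified: " + "; ".join(report.messages)
                )
        fit = fit_model(self.transformed, self.spec_g, self.spec_e, config)
        if se:
            vs = implied_variance_matrices(fit.theta_hat, self.spec_g, self.spec_e)
            fit.ai_matrix = average_information(self.transformed, vs, fit.theta_hat)
            fit.theta_cov = theta_covariance(fit.ai_matrix)
        return MgremlResults(self, fit)


class MgremlResults:
    """Fitted MGREML model: estimates, uncertainties and tests."""

    def __init__(self, model: MgremlModel, fit: FitResult) -> None:
        self.model = model
        self.fit = fit
        self.variance_structure = fix_loading_signs(
            implied_variance_matrices(fit.theta_hat, model.spec_g, model.spec_e)
        )
        h2, rho_g, rho_e = heritability_and_correlations(self.variance_structure)
        self._h2, self._rho_g, self._rho_e = h2, rho_g, rho_e
        self._report: HeritabilityReport | None = None
        self._fixed: FixedEffectsReport | None = None

    # -- point estimates ----------------------------------------------------
    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def trait_labels(self) -> list[str]:
        return self.model.phenotypes.trait_labels

    @property
    def h2(self) -> np.ndarray:
        """SNP-based heritability per trait."""
        return self._h2

    @property
    def rho_g(self) -> np.ndarray:
        """Genetic correlation matrix (NaN where genetic variance is zero)."""
        return self._rho_g

    @property
    def rho_e(self) -> np.ndarray:
        return self._rho_e

    @property
    def V_G(self) -> np.ndarray:
        return self.variance_structure.V_G

    @property
    def V_E(self) -> np.ndarray:
        return self.variance_structure.V_E

    # -- uncertainties -------------------------------------------------------
    @property
    def heritability_report(self) -> HeritabilityReport:
        if self._report is None:
            if self.fit.theta_cov is None:
                self._report = HeritabilityReport(
                    trait_labels=self.trait_labels,
                    h2=self._h2,
                    h2_se=None,
                    rhoG=self._rho_g,
                    rhoG_se=None,
                    rhoE=self._rho_e,
                    rhoE_se=None,
                )
            else:
                self._report = delta_method_ses(
                    self.fit.theta_hat,
                    self.fit.theta_cov,
                    self.model.spec_g,
                    self.model.spec_e,
                    trait_labels=self.trait_labels,
                )
        return self._report

    @property
    def h2_se(self) -> np.ndarray | None:
        return self.heritability_report.h2_se

    @property
    def rho_g_se(self) -> np.ndarray | None:
        return self.heritability_report.rhoG_se

    @property
    def fixed_effects(self) -> FixedEffectsReport:
        if self._fixed is None:
            self._fixed = gls_fixed_effects(self.model.transformed, self.variance_structure)
        return self._fixed

    # -- model comparison ----------------------------------------------------
    def compare(self, nested: "MgremlResults") -> LrtResult:
        """Likelihood-ratio test of this (main) model against a nested one."""
        df = lrt_degrees_of_freedom(
            (self.model.spec_g, self.model.spec_e),
            (nested.model.spec_g, nested.model.spec_e),
        )
        return likelihood_ratio_test(self.fit, nested.fit, df)

    # -- presentation ----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "MGREML estimation results",
            "=" * 60,
            f"traits: {len(self.trait_labels)}   samples (post-alignment): {self.model.phenotypes.n}",
            f"leading PCs removed: {self.model.drop_leading_pcs}",
            f"free coefficients: G={self.model.spec_g.n_free}  E={self.model.spec_e.n_free}",
            f"log-likelihood: {self.loglik:.6f}   converged: {self.converged} "
            f"({self.fit.n_iter} iterations)",
            "",
            "SNP-based heritability",
            "-" * 60,
        ]
        se = self.h2_se if self.fit.theta_cov is not None else None
        for i, lab in enumerate(self.trait_labels):
            se_txt = f"  (SE {se[i]:.4f})" if se is not None else ""
            lines.append(f"  {lab:<20s} h2 = {self._h2[i]:.4f}{se_txt}")
        lines += ["", "Genetic correlations (lower triangle)", "-" * 60]
        for i in range(1, len(self.trait_labels)):
            row = "  ".join(
                "   nan" if not np.isfinite(self._rho_g[i, j]) else f"{self._rho_g[i, j]:+.3f}"
                for j in range(i)
            )
            lines.append(f"  {self.trait_labels[i]:<20s} {row}")
        return "\n".join(lines)

    def save(self, out_prefix: str | Path) -> list[Path]:
        """Write tab-delimited report tables plus a full-precision JSON sidecar."""
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        def _path(suffix: str) -> Path:
            p = out_prefix.with_name(out_prefix.name + suffix)
            written.append(p)
            return p

        rep = self.heritability_report
        with open(_path(".HsqSNP.out"), "w") as fh:
            header = "trait\th2" + ("\tse" if rep.h2_se is not None else "")
            fh.write(header + "\n")
            for i, lab in enumerate(self.trait_labels):
                row = f"{lab}\t{self._h2[i]:.6g}"
                if rep.h2_se is not None:
                    row += f"\t{rep.h2_se[i]:.6g}"
                fh.write(row + "\n")
        _write_square(_path(".RhoG.out"), self.trait_labels, self._rho_g)
        _write_square(_path(".RhoE.out"), self.trait_labels, self._rho_e)
        if rep.rhoG_se is not None:
            _write_square(_path(".RhoG.SE.out"), self.trait_labels, rep.rhoG_se)
            _write_square(_path(".RhoE.SE.out"), self.trait_labels, rep.rhoE_se)
        if self.model.transformed.n_fixed > 0:
            fe = self.fixed_effects
            with open(_path(".GLS.out"), "w") as fh:
                fh.write("trait\tcovariate\tbeta\tse\n")
                for (trait, cov), b, s in zip(fe.labels, fe.beta, fe.beta_se):
                    fh.write(f"{trait}\t{cov}\t{b:.6g}\t{s:.6g}\n")
        sidecar = {
            "package_version": _version,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.fit.n_iter,
            "L": self.model.drop_leading_pcs,
            "theta": self.fit.theta_hat.values.tolist(),
            "theta_index": [list(ix) for ix in self.fit.theta_hat.index],
            "V_G": self.V_G.tolist(),
            "V_E": self.V_E.tolist(),
            "h2": self._h2.tolist(),
        }
        with open(_path(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)
        return written


def _write_square(path: Path, labels: list[str], mat: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("trait\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, mat):
            fh.write(lab + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
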