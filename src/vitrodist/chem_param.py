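"""Chemical identity, properties, and parameterization rules.

A :class:`Chemical` carries the physicochemical parameters required by the
in vitro distribution models: molar mass, melting point, octanol–water and
air–water partition coefficients, aqueous solubility, salting-out constant,
acid/base dissociation constants, and the pH-7.4 distribution ratios toward
serum albumin and phospholipid liposomes.

Three parameterization rules are implemented here:

* **Speciation.**  An ionizable organic chemical (IOC) is classified by
  comparing its strongest acidic/basic pKa with the assay pH.  A pKa that
  puts the compound predominantly in its neutral form across the whole
  relevant range — an acidic pKa at least 2 log units above the pH, or a
  basic pKa at least 2 log units below — is ignored and the compound treated
  as neutral.  The neutral fraction of a retained pKa follows the
  Henderson–Hasselbalch relation.

* **Salting-out constant.**  When no measured Setschenow constant is
  supplied it is estimated from hydrophobicity:
  ``K_salt = 0.04·logKow + 0.114`` (L/mol).

* **Distribution ratios.**  When measured albumin–water / liposome–water
  distribution ratios are absent they are predicted by linear regressions on
  log Kow; for IOCs the regression input is first corrected to the
  octanol–water *distribution* ratio, log D_OW = log Kow + log10(f_neutral),
  so only the neutral species is assumed to partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .config import ChemParamConfig
from .errors import ParameterizationError, ValidationError

NEUTRAL = "neutral"
ACID = "acid"
BASE = "base"
IOC_CLASSES = (NEUTRAL, ACID, BASE)


@dataclass
class SpeciationResult:
    """Outcome of the pKa screening rule at a given pH."""

    ioc_class: str
    effective_pka: float | None
    f_neutral: float


@dataclass
class Chemical:
    """One chemical with the parameters used by the distribution models.

    Optional fields left as ``None`` can be derived by
    :func:`validate_chemical`; the ``provenance`` map records, per derived
    field, whether the stored value was measured (supplied) or derived.
    """

    id: str
    name: str
    mw: float  # g/mol
    mp: float  # °C
    log_kow: float
    solubility_w: float  # mg/L
    log_kaw: float | None = None
    k_salt: float | None = None  # L/mol
    pka_acid: float | None = None
    pka_base: float | None = None
    ioc_class: str | None = None
    h37: float | None = None  # Pa·m³/mol
    vb: float | None = None  # cm³/mol
    log_d_bsa_w: float | None = None
    log_d_lip_w: float | None = None
    provenance: dict = field(default_factory=dict)


def resolve_speciation(
    pka_acid: float | None = None,
    pka_base: float | None = None,
    ph: float = 7.4,
    window: float = 2.0,
    expect_ionizable: bool = False,
) -> SpeciationResult:
    """Classify a chemical as neutral/acid/base at ``ph`` and compute f_neutral.

    An acidic pKa at least ``window`` log units above ``ph`` is ignored
    (compound predominantly neutral); likewise a basic pKa at least
    ``window`` log units below ``ph``.  If both an acidic and a basic pKa
    survive the screen, the one closer to ``ph`` is retained (zwitterions are
    outside the applicability domain).  The neutral fraction of the retained
    species is the base-10 Henderson–Hasselbalch form
    ``f_neutral = 1/(1 + 10^(s·(ph − pKa)))`` with s = +1 for acids and −1
    for bases.

    Parameters
    ----------
    expect_ionizable
        If True and neither pKa is supplied, raise: the caller asserted the
        chemical is an IOC, so a missing pKa is inconsistent input.
    """
    if not (0.0 <= ph <= 14.0):
        raise ValidationError("ph", f"pH {ph} outside [0, 14]")
    for name, value in (("pka_acid", pka_acid), ("pka_base", pka_base)):
        if value is not None and not (-5.0 <= value <= 20.0):
            raise ValidationError(name, f"pKa {value} outside [-5, 20]")
    if expect_ionizable and pka_acid is None and pka_base is None:
        raise ValidationError("pka", "chemical asserted ionizable but no pKa supplied")

    acid_ok = pka_acid is not None and pka_acid < ph + window
    base_ok = pka_base is not None and pka_base > ph - window

    if acid_ok and base_ok:
        # tie-break: classify by the pKa closest to the system pH
        if abs(pka_acid - ph) <= abs(pka_base - ph):
            base_ok = False
        else:
            acid_ok = False

    if acid_ok:
        f_neutral = 1.0 / (1.0 + 10.0 ** (ph - pka_acid))
        return SpeciationResult(ACID, pka_acid, f_neutral)
    if base_ok:
        f_neutral = 1.0 / (1.0 + 10.0 ** (pka_base - ph))
        return SpeciationResult(BASE, pka_base, f_neutral)
    return SpeciationResult(NEUTRAL, None, 1.0)


def ksalt_from_logkow(log_kow: float) -> float:
    """Setschenow (salting-out) constant in L/mol from log Kow.

    ``K_salt = 0.04·logKow + 0.114``; used only when no measured value is
    supplied.
    """
    if not math.isfinite(log_kow):
        raise ValidationError("log_kow", "log_kow must be finite")
    return 0.04 * log_kow + 0.114


def predict_distribution_ratios(
    chem: Chemical,
    ph: float = 7.4,
    config: ChemParamConfig | None = None,
) -> tuple[float, float]:
    """Predict (log D_BSA/w, log D_lip/w) at ``ph`` from log Kow.

    For neutral chemicals the configured linear regressions are applied
    directly to log Kow.  For IOCs log Kow is first corrected to
    log D_OW = log Kow + log10(f_neutral) and the same regressions applied,
    i.e. only the neutral species partitions (a fixed ionic log-offset can be
    enabled in the configuration).  Measured values stored on the chemical
    take precedence over prediction.
    """
    cfg = config or ChemParamConfig()
    if chem.log_kow is None:
        raise ParameterizationError(f"{chem.id}: log_kow required to predict distribution ratios")
    spec = resolve_speciation(chem.pka_acid, chem.pka_base, ph, cfg.speciation_window)
    log_d_ow = chem.log_kow + math.log10(spec.f_neutral)
    log_bsa = cfg.bsa_slope * log_d_ow + cfg.bsa_intercept
    log_lip = cfg.lip_slope * log_d_ow + cfg.lip_intercept
    f_ion = 1.0 - spec.f_neutral
    if cfg.ion_log_offset is not None and spec.ioc_class != NEUTRAL and f_ion > 0:
        # optional fixed log-offset ionic sorption term added to the
        # neutral-species contribution
        ion_bsa = cfg.bsa_slope * chem.log_kow + cfg.bsa_intercept + cfg.ion_log_offset
        ion_lip = cfg.lip_slope * chem.log_kow + cfg.lip_intercept + cfg.ion_log_offset
        log_bsa = math.log10(10.0**log_bsa + f_ion * 10.0**ion_bsa)
        log_lip = math.log10(10.0**log_lip + f_ion * 10.0**ion_lip)
    if chem.log_d_bsa_w is not None:
        log_bsa = chem.log_d_bsa_w
    if chem.log_d_lip_w is not None:
        log_lip = chem.log_d_lip_w
    return log_bsa, log_lip


def validate_chemical(chem: Chemical, config: ChemParamConfig | None = None) -> Chemical:
    """Check invariants and fill derivable fields.

    Fills ``k_salt``, ``log_d_bsa_w``, ``log_d_lip_w`` and ``ioc_class`` when
    absent, tagging each filled field as ``"derived"`` in ``provenance``
    (supplied fields are tagged ``"measured"``).  Raises
    :class:`ValidationError` naming the offending field on any violated
    invariant.
    """
    cfg = config or ChemParamConfig()
    if chem.mw is None or chem.mw <= 0:
        raise ValidationError("mw", f"molar mass must be positive, got {chem.mw}")
    if chem.solubility_w is None or chem.solubility_w <= 0:
        raise ValidationError("solubility_w", f"solubility must be positive, got {chem.solubility_w}")

    spec = resolve_speciation(chem.pka_acid, chem.pka_base, cfg.ph, cfg.speciation_window)
    provenance = dict(chem.provenance)
    out = replace(chem)

    if chem.ioc_class is None:
        out.ioc_class = spec.ioc_class
        provenance["ioc_class"] = "derived"
    else:
        if chem.ioc_class not in IOC_CLASSES:
            raise ValidationError("ioc_class", f"unknown class {chem.ioc_class!r}")
        if chem.ioc_class != spec.ioc_class:
            raise ValidationError(
                "ioc_class",
                f"declared {chem.ioc_class!r} but pKa screen at pH {cfg.ph} gives {spec.ioc_class!r}",
            )
        if chem.ioc_class == ACID and chem.pka_acid is None:
            raise ValidationError("pka_acid", "acid class requires pka_acid")
        if chem.ioc_class == BASE and chem.pka_base is None:
            raise ValidationError("pka_base", "base class requires pka_base")
        provenance["ioc_class"] = "measured"

    if chem.k_salt is None:
        out.k_salt = ksalt_from_logkow(chem.log_kow)
        provenance["k_salt"] = "derived"
    else:
        provenance["k_salt"] = "measured"

    log_bsa, log_lip = predict_distribution_ratios(out, cfg.ph, cfg)
    if chem.log_d_bsa_w is None:
        out.log_d_bsa_w = log_bsa
        provenance["log_d_bsa_w"] = "derived"
    else:
        provenance["log_d_bsa_w"] = "measured"
    if chem.log_d_lip_w is None:
        out.log_d_lip_w = log_lip
        provenance["log_d_lip_w"] = "derived"
    else:
        provenance["log_d_lip_w"] = "measured"

    out.provenance = provenance
    return out
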