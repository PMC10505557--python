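# lignoporo

Analysis pipelines for the physico-chemical characterisation of (engineered)
lignocellulosic biomass — the measurements typically used to show that a
cell-wall modification changes how wood holds water:

* **Dynamic vapour sorption (DVS)** — convert mass-vs-time kinetic traces
  recorded under stepped relative humidity into equilibrium
  sorption/desorption isotherms, and fit the **Park model**

  $$M(a_w) = \frac{A_L\,b_L\,a_w}{1+b_L\,a_w} + k_H\,a_w + n\,k_H^n\,k_a\,a_w^n$$

  (Langmuir adsorption + Henry dissolution + water clustering), with fit
  quality reported as the mean relative percentage deviation modulus
  $\mathrm{MRD} = \frac{100}{N}\sum_i |m_i - m_{p,i}|/m_i$ (< 10% is the
  conventional good-fit bound).

* **DSC thermoporosimetry** — invert stepwise-isothermal melting thermograms
  into pore-size distributions through the Gibbs–Thomson relation

  $$D = \frac{4\,T_0\,\gamma\,\cos\theta}{(T_m - T_0)\,\rho\,H_f}$$

  with $T_0 = 273.15\,$K, $\gamma = 12.1\,$mJ m⁻², $\theta = 180°$,
  $\rho = 1000\,$kg m⁻³, $H_f = 334\,$J g⁻¹ (so a 1 K melting-point
  depression corresponds to ≈ 39.6 nm pores, 10 K to ≈ 4 nm).

* **Immunofluorescence quantification** — maximum projection of two-channel
  z-stacks, a counterstain-thresholded cell-wall mask (manual or Otsu,
  optional ROI polygon), masked mean intensity of the immunolabelled
  channel, and between-genotype fold changes with section-level bootstrap
  confidence intervals.

* **Group statistics** — the standard decision tree for grouped phenotype
  data: Shapiro–Wilk + Bartlett assumption gate, one-way ANOVA with Tukey
  HSD (exact studentized-range p-values) or Kruskal–Wallis with
  Holm-adjusted rank-sum comparisons, and a compact letter display at
  α = 0.05 verified against the pairwise matrix on every output.

* **Derived metrics** — green density ($R = m_\text{dry}/V_\text{wet}$) and
  percent change.

A **synthetic-data generator** (`lignoporo.simulate`) produces
ground-truth-labelled inputs for every stage — Park-model DVS kinetics, DSC
melting traces encoding known pore distributions, honeycomb-lattice
two-channel image stacks, and grouped draws from stated distributions — so
every pipeline is testable end to end without instrument data.

## Worked example

Simulate a full DVS campaign at wood-like conditions (dry mass 20 mg,
activity ladder 0.1→0.9→0, τ = 20 min, slight balance noise), rebuild the
isotherm from the kinetics and fit the Park model:

```python
import lignoporo as lp

trace = lp.gen_dvs_kinetics(noise_sd=0.002, seed=42)
sorption, desorption = lp.build_isotherm(trace)
res = lp.ParkSorptionModel.from_isotherm(sorption).fit()
print(res.summary())
```

```
Park sorption model fit
===============================================
n points                     9
converged                 True
MRD (%)                 0.0070   (<10: good fit)
RSS                    2.8e-06
-----------------------------------------------
param         estimate       std err
A_L            2.02732     4.694e-22
b_L            14.3798      5.06e-24
k_H            11.9627     4.171e-21
k_a        1.03463e-08     5.408e-13
n               7.9958     1.389e-20
===============================================
```

The fitted curve reproduces the generator's ground truth (A_L=2, b_L=15,
k_H=12, k_a=1e-8, n=8): an MRD of 0.007% is far below the 10% good-fit
bound, and `res.predict(0.9)` returns 27.44% — the mass gain at 90% RH, the
figure used to compare hygroscopicity between genotypes.

The thermoporosimetry pipeline is symmetric: encode a known 5-bin mesopore
distribution (4–32 nm, plus 20% bulk water) in a synthetic thermogram and
invert it:

```python
dist = lp.Thermoporometry(thermogram, program).fit()
print(dist.summary())
```

```
Pore-size distribution (Gibbs-Thomson)
==============================================
  d_low (nm) d_high (nm)   water (%)
        4.00        6.06       16.63
        6.06        9.19       23.72
        9.19       13.93       13.47
       13.93       21.11       21.20
       21.11       32.00        4.85
----------------------------------------------
free (bulk) water: 20.13 %
total freezing water: 2.971 mg
==============================================
```

Each row is the share of freezing water melting in one isothermal step,
i.e. held in pores of that diameter range; the programmed fractions are
recovered to well under 2 percentage points despite heat-flow noise.

Everything is also reachable from the shell:

```bash
lignoporo simulate dvs --out sim/ --seed 3
lignoporo dvs-fit --trace sim/trace.csv --out fit.json
lignoporo dsc-pores --thermogram t.csv --program p.json --out dist.csv
lignoporo quantify-image --stack img.tif --threshold otsu --out q.csv
lignoporo compare-groups --data groups.csv --out stats.json
```

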