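# Coupled branching simulation: desk-scale validation regime.
sigma = 2.0
rho = 20.0
mu = 5e-8
s = 0.05
L = 200.0
seed = 7
sites = 2000          # mutational sites represented (influx = rho*L^2*mu*sites)
burn_in = 200.0       # 10/s generations
record_every = 80.0   # 4/s generations: successive records ~independent
total_time = 5000.0
kernels = [
  { kind = "gaussian", width = 8.94, center = [100.0, 100.0] },
  { kind = "uniform" },
]
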