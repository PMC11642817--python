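# Synthetic cohort: clustered rare-variant carriers + uniform non-carriers.
sigma = 40.0
rho = 0.06
mu = 1e-6            # per-site rate; per-class defaults override in the API
L = 1000.0
seed = 11
n_individuals = 60000
sites_per_class = 1000

[classes]            # selection coefficient per annotation-severity class
lof = 0.1
missense = 0.01
synonymous = 0.001

[class_mu]           # per-class mutation supply (comparable discoverable sites)
lof = 3.2e-6
missense = 7.0e-7
synonymous = 1.5e-7
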