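analysis
approach
assay
blood
carrier
cell
clinic
cohort
control
culture
data
dna
evaluation
examination
expression
family
female
frequency
gene
genome
group
individual
laboratory
level
male
measurement
method
mitochondria
molecular
muscle
normal
observation
onset
population
presentation
proband
profile
protocol
region
report
result
sample
screening
sequence
sequencing
skeletal
study
subject
symptom
test
tissue
value
weather
mild
overall
previous
present
observed
described
detected
identified
performed
obtained
compared
measured
collected
confirmed
evaluated
examined
included
reviewed
suggested
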