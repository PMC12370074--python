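species,model,aic,delta_aic,weight,model_likelihood,k,deviance
mugger,"psi(.),p(survey)",550.62,0.00,1.00,1.00,6,538.62
mugger,"psi(.),p(.)",569.29,18.67,0.00,0.00,2,565.29
gharial,"psi(.),p(survey)",633.88,0.00,0.94,1.00,6,621.88
gharial,"psi(.),p(.)",639.35,5.47,0.06,0.06,2,635.35
crocodile,"psi(.),p(survey)",911.97,0.00,1.00,1.00,6,899.97
crocodile,"psi(.),p(.)",924.79,12.82,0.00,0.00,2,920.79
pair,"psiG,psiM,phi(.),pG=rG,pM=rM,delta",1162.39,0.00,0.76,1.00,8,1146.39
pair,"psiG,psiM,phi=1,pG=rG,pM=rM,delta",1164.70,2.31,0.24,0.32,7,1150.70
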